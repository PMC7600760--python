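"""Phylogenetic signal in between-taxon niche differences.

The null-model framework for assembly inference is only interpretable if
ecologically similar taxa are also phylogenetic neighbours, at least over
short phylogenetic distances.  This module computes per-taxon environmental
optima (relative-abundance-weighted means), niche distances between taxa,
and a Mantel correlogram of niche distance against patristic distance with
permutation tests and Holm correction across distance classes.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from skbio import DistanceMatrix

from .io import CommunityTable, relative_abundance

logger = logging.getLogger(__name__)

__all__ = ["niche_optima", "niche_distance", "mantel_correlogram"]


def niche_optima(table: CommunityTable, env: pd.DataFrame) -> pd.DataFrame:
    """Abundance-weighted environmental optimum of every taxon.

    optimum(taxon, v) = sum_s f_s(taxon) * env_s(v) / sum_s f_s(taxon),
    with f_s the taxon's relative abundance in sample s.  Taxa absent from
    every sample are excluded (logged).  Returns taxa x variables.
    """
    env = env.loc[table.sample_ids]
    if env.isna().any().any():
        bad = env.columns[env.isna().any()].tolist()
        raise ValueError(f"missing values in environmental columns: {bad}")
    f = relative_abundance(table).to_numpy()          # samples x taxa
    w = f.sum(axis=0)                                 # per-taxon total weight
    present = w > 0
    if not present.all():
        logger.info("excluding %d taxa absent everywhere", (~present).sum())
    opt = (f[:, present].T @ env.to_numpy()) / w[present, None]
    return pd.DataFrame(opt, index=np.asarray(table.taxon_ids)[present],
                        columns=env.columns)


def niche_distance(optima: pd.DataFrame) -> DistanceMatrix:
    """Euclidean niche distance between taxa on z-standardized optima.

    Each optimum column is standardized (mean 0, population sd 1) before the
    Euclidean distance, so variables with incommensurable units contribute
    comparably.  Constant columns cannot be standardized and are dropped
    with a warning.
    """
    X = optima.to_numpy(dtype=float)
    sd = X.std(axis=0)
    keep = sd > 0
    if not keep.all():
        logger.warning("dropping constant optimum columns: %s",
                       list(optima.columns[~keep]))
    if not keep.any():
        raise ValueError("all optimum columns constant")
    Z = (X[:, keep] - X[:, keep].mean(axis=0)) / sd[keep]
    from scipy.spatial.distance import pdist, squareform

    return DistanceMatrix(squareform(pdist(Z)), ids=list(optima.index))


def _sturges(n_pairs: int) -> int:
    return int(np.floor(np.log2(n_pairs))) + 1


def mantel_correlogram(
    nicheD: DistanceMatrix,
    phyloD: DistanceMatrix,
    n_classes: int | None = None,
    n_perm: int = 999,
    seed: int = 0,
) -> pd.DataFrame:
    """Mantel correlogram of niche distance across phylogenetic distance classes.

    Distance classes partition the range of the patristic distances (Sturges
    rule on the number of pairs when ``n_classes`` is None).  Per class the
    statistic is the Mantel correlation between the niche-distance matrix and
    the binary within-class indicator, sign-flipped so that positive values
    mean positive autocorrelation (ecologically similar taxa at that
    phylogenetic distance).  Two-sided permutation p-values shuffle taxon
    labels of the niche matrix jointly; Holm step-down correction is applied
    across the testable classes.

    Returns a DataFrame with one row per class: class_index, class_midpoint,
    mantel_r, p_raw, p_holm, n_pairs_in_class, testable.
    """
    if n_perm < 99:
        raise ValueError("n_perm must be >= 99")
    if list(nicheD.ids) != list(phyloD.ids):
        nicheD = nicheD.filter(phyloD.ids)
    n = nicheD.shape[0]
    iu = np.triu_indices(n, k=1)
    x_full = nicheD.data
    pvec = phyloD.data[iu]
    N = pvec.size
    k = n_classes or _sturges(N)
    edges = np.linspace(pvec.min(), pvec.max(), k + 1)
    cls = np.clip(np.digitize(pvec, edges[1:-1]), 0, k - 1)
    mid = 0.5 * (edges[:-1] + edges[1:])
    n_in = np.bincount(cls, minlength=k).astype(float)

    xvec = x_full[iu]
    xbar, sx = xvec.mean(), xvec.std()
    if sx == 0:
        raise ValueError("niche distances are constant")
    ybar = n_in / N
    sy = np.sqrt(ybar * (1.0 - ybar))

    def stats_from(xmat: np.ndarray) -> np.ndarray:
        # r_c = -cor(x, indicator_c); mean/sd of x invariant under relabeling
        S = np.bincount(cls, weights=xmat[iu], minlength=k)
        with np.errstate(invalid="ignore", divide="ignore"):
            r = (S / N - xbar * ybar) / (sx * sy)
        return -r

    r_obs = stats_from(x_full)
    rng = np.random.default_rng(seed)
    exceed = np.zeros(k)
    for _ in range(n_perm):
        p = rng.permutation(n)
        exceed += np.abs(stats_from(x_full[np.ix_(p, p)])) >= np.abs(r_obs) - 1e-12
    p_raw = (exceed + 1.0) / (n_perm + 1.0)

    testable = n_in >= 2
    p_holm = np.full(k, np.nan)
    p_holm[testable] = _holm(p_raw[testable])
    return pd.DataFrame({
        "class_index": np.arange(1, k + 1),
        "class_midpoint": mid,
        "mantel_r": np.where(testable, r_obs, np.nan),
        "p_raw": np.where(testable, p_raw, np.nan),
        "p_holm": p_holm,
        "n_pairs_in_class": n_in.astype(int),
        "testable": testable,
    })


def _holm(p: np.ndarray) -> np.ndarray:
    """Holm step-down adjustment (monotone, capped at 1)."""
    m = len(p)
    order = np.argsort(p)
    adj = np.empty(m)
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, (m - rank) * p[idx])
        adj[idx] = min(1.0, running)
    return adj
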