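"""Two-step null-model quantification of community assembly processes.

For every pair of communities the pipeline computes:

1. the abundance-weighted beta mean nearest taxon distance (βMNTD) and its
   standardized effect size against a tip-shuffle null (βNTI = β-nearest
   taxon index).  |βNTI| > 2 indicates selection: βNTI > +2 heterogeneous
   selection (environments pushing communities apart), βNTI < −2 homogeneous
   selection (similar environments pulling them together);
2. for the remaining (|βNTI| < 2) pairs, the modified Raup–Crick metric on
   Bray–Curtis (RC_bray), the rank-standardized deviation of observed
   dissimilarity from a richness- and abundance-preserving random-assembly
   null, rescaled to [−1, 1].  RC_bray > +0.95 indicates dispersal
   limitation, RC_bray < −0.95 homogenizing dispersal, and |RC_bray| < 0.95
   turnover undominated by any single process.

Fractions of each process over all pairwise comparisons within a group
(e.g. a season) summarize the balance of deterministic and stochastic
assembly.
"""

from __future__ import annotations

import logging
from typing import Iterable

import numpy as np
import pandas as pd
from skbio import DistanceMatrix, TreeNode

from .io import CommunityTable

logger = logging.getLogger(__name__)

PROCESSES = (
    "heterogeneous_selection",
    "homogeneous_selection",
    "dispersal_limitation",
    "homogenizing_dispersal",
    "undominated",
)

_TIE_TOL = 1e-12


class DegeneratePairError(ValueError):
    """Null distribution has zero spread; the pair cannot be standardized."""


def patristic_matrix(tree: TreeNode) -> DistanceMatrix:
    """Tip-to-tip patristic distances (sum of branch lengths on the path)."""
    return tree.tip_tip_distances()


def beta_mntd(freq_i: pd.Series, freq_j: pd.Series,
              phyloD: DistanceMatrix) -> float:
    """Abundance-weighted beta mean nearest taxon distance between two samples.

    βMNTD = 0.5 * [ Σ_{a∈i} f_a · min_{b∈j} d(a,b)
                  + Σ_{b∈j} f_b · min_{a∈i} d(a,b) ]

    with sums over taxa of positive frequency and d the patristic distance.
    A taxon shared by both samples contributes zero (its nearest taxon in
    the other community is itself).
    """
    ids = list(phyloD.ids)
    fi = freq_i.reindex(ids, fill_value=0.0).to_numpy(dtype=float)
    fj = freq_j.reindex(ids, fill_value=0.0).to_numpy(dtype=float)
    ia, ib = np.flatnonzero(fi > 0), np.flatnonzero(fj > 0)
    if ia.size == 0 or ib.size == 0:
        raise ValueError("empty community in beta_mntd")
    return _bmntd(fi[ia], fj[ib], phyloD.data[np.ix_(ia, ib)])


def _bmntd(fA: np.ndarray, fB: np.ndarray, sub: np.ndarray) -> float:
    # sub is the patristic submatrix rows=present-in-i, cols=present-in-j
    return 0.5 * (fA @ sub.min(axis=1) + fB @ sub.min(axis=0))


def _present(freq: np.ndarray):
    idx = np.flatnonzero(freq > 0)
    return idx, freq[idx] / freq[idx].sum()


def bnti_pair(table: CommunityTable, tree: TreeNode, i: str, j: str,
              n_null: int = 999, seed: int = 0):
    """βMNTD, tip-shuffle null moments and βNTI for one sample pair.

    Each null replicate permutes tip labels uniformly over the tree of the
    analysis taxon pool (here: taxa present in the table) and re-evaluates
    βMNTD; βNTI = (βMNTD_obs − mean_null) / sd_null.

    Returns ``(bmntd_obs, null_mean, null_sd, bnti)``.
    """
    if n_null < 99:
        raise ValueError("n_null must be >= 99")
    pool = table.drop_empty_taxa()
    D = patristic_matrix(tree).filter(pool.taxon_ids).data
    f = pool.counts.loc[[i, j]].to_numpy(dtype=float)
    idxA, fA = _present(f[0])
    idxB, fB = _present(f[1])
    if idxA.size == 0 or idxB.size == 0:
        raise ValueError("empty community")
    obs = _bmntd(fA, fB, D[np.ix_(idxA, idxB)])
    rng = np.random.default_rng(seed)
    null = np.empty(n_null)
    n_pool = D.shape[0]
    for r in range(n_null):
        perm = rng.permutation(n_pool)
        null[r] = _bmntd(fA, fB, D[np.ix_(perm[idxA], perm[idxB])])
    mu, sd = null.mean(), null.std(ddof=1)
    if sd <= 0:
        raise DegeneratePairError(
            f"tip-shuffle null is invariant for pair ({i}, {j})")
    return obs, mu, sd, (obs - mu) / sd


def _rc_pool_stats(counts: np.ndarray):
    """Occupancy and mean relative abundance over the pool samples."""
    totals = counts.sum(axis=1, keepdims=True)
    occupancy = (counts > 0).mean(axis=0)
    mean_rel = (counts / totals).mean(axis=0)
    return occupancy, mean_rel


def _bray_curtis(u: np.ndarray, v: np.ndarray) -> float:
    denom = u.sum() + v.sum()
    return float(np.abs(u - v).sum() / denom)


def _assemble_null(richness: int, total: int, occupancy: np.ndarray,
                   mean_rel: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """One random community: occupancy-weighted membership, abundance fill."""
    n_pool = occupancy.size
    chosen = rng.choice(n_pool, size=richness, replace=False,
                        p=occupancy / occupancy.sum())
    out = np.zeros(n_pool)
    out[chosen] = 1.0
    if total > richness:
        p = mean_rel[chosen]
        out[chosen] += rng.multinomial(total - richness, p / p.sum())
    return out


def raup_crick_bray(table: CommunityTable, i: str, j: str,
                    n_null: int = 999, seed: int = 0,
                    pool_samples: Iterable[str] | None = None):
    """Modified Raup–Crick metric on Bray–Curtis for one sample pair.

    Each null replicate rebuilds both communities from the taxon pool: the
    sample's observed richness is drawn without replacement with probability
    proportional to pool occupancy, then the sample's observed read total is
    distributed over the drawn taxa proportionally to pool mean relative
    abundance (each drawn taxon keeps at least one read).  The observed
    Bray–Curtis dissimilarity is ranked within the null distribution:

        RC_bray = 2 * [ (#(null < obs) + 0.5 * #(null = obs)) / n_null ] − 1

    Returns ``(bc_obs, rc_bray)``.
    """
    if n_null < 99:
        raise ValueError("n_null must be >= 99")
    pool_ids = list(pool_samples) if pool_samples is not None else table.sample_ids
    pool_counts = table.counts.loc[pool_ids]
    keep = pool_counts.sum(axis=0) > 0
    pool_counts = pool_counts.loc[:, keep].to_numpy(dtype=float)
    occupancy, mean_rel = _rc_pool_stats(pool_counts)
    x = table.counts.loc[[i, j], keep.index[keep]].to_numpy(dtype=float)
    if x[0].sum() == 0 or x[1].sum() == 0:
        raise ValueError("empty community")
    rich = (x > 0).sum(axis=1)
    totals = x.sum(axis=1).astype(int)
    if (rich > occupancy.size).any():
        raise ValueError("sample richness exceeds pool taxon count")
    bc_obs = _bray_curtis(x[0], x[1])
    rng = np.random.default_rng(seed)
    less = ties = 0
    for _ in range(n_null):
        u = _assemble_null(int(rich[0]), int(totals[0]), occupancy, mean_rel, rng)
        v = _assemble_null(int(rich[1]), int(totals[1]), occupancy, mean_rel, rng)
        bc = _bray_curtis(u, v)
        if abs(bc - bc_obs) <= _TIE_TOL:
            ties += 1
        elif bc < bc_obs:
            less += 1
    rc = 2.0 * ((less + 0.5 * ties) / n_null) - 1.0
    return bc_obs, rc


def classify_process(bnti: float, rc_bray: float) -> str:
    """Five-process classification from (βNTI, RC_bray).

    Strict thresholds: βNTI > +2 heterogeneous selection, βNTI < −2
    homogeneous selection; otherwise RC_bray > +0.95 dispersal limitation,
    RC_bray < −0.95 homogenizing dispersal, else undominated.  Boundary
    values fall on the stochastic/undominated side.
    """
    if not -1.0 - 1e-9 <= rc_bray <= 1.0 + 1e-9:
        raise ValueError("rc_bray outside [-1, 1]")
    if bnti > 2.0:
        return "heterogeneous_selection"
    if bnti < -2.0:
        return "homogeneous_selection"
    if rc_bray > 0.95:
        return "dispersal_limitation"
    if rc_bray < -0.95:
        return "homogenizing_dispersal"
    return "undominated"


def quantify_processes(table: CommunityTable, tree: TreeNode,
                       meta: pd.DataFrame | None = None,
                       group_col: str | None = None,
                       n_null: int = 999, seed: int = 0,
                       pool: str = "group",
                       between_col: str | None = None):
    """Classify every within-group sample pair and summarize process fractions.

    ``pool="group"`` restricts the null taxon pool (tip shuffles and
    Raup–Crick occupancy/abundance statistics) to each group's samples;
    ``pool="global"`` uses the whole table.  One tip permutation per null
    replicate is shared across all pairs of a group; Raup–Crick streams are
    spawned per pair from the master seed, so results do not depend on
    evaluation order.  ``between_col`` optionally restricts the summary to
    pairs whose samples differ in that metadata column (e.g. between-site
    comparisons only).

    Returns ``(pairs, summary)``: a per-pair DataFrame (βMNTD, null moments,
    βNTI, Bray–Curtis, RC_bray, process) and a per-group DataFrame of process
    fractions, pair counts and the selection : dispersal ratio.
    """
    if pool not in ("group", "global"):
        raise ValueError("pool must be 'group' or 'global'")
    if group_col is not None:
        if meta is None or group_col not in meta.columns:
            raise ValueError(f"group column {group_col!r} not in metadata")
        groups = meta.loc[table.sample_ids, group_col]
    else:
        groups = pd.Series("all", index=table.sample_ids)

    D_full = patristic_matrix(tree)
    master = np.random.SeedSequence(seed)
    pair_rows = []
    for g_i, (gname, members) in enumerate(groups.groupby(groups)):
        samples = list(members.index)
        if len(samples) < 2:
            logger.warning("group %s has < 2 samples; skipped", gname)
            continue
        pool_ids = table.sample_ids if pool == "global" else samples
        sub = CommunityTable(table.counts.loc[pool_ids]).drop_empty_taxa()
        D = D_full.filter(sub.taxon_ids).data
        counts = sub.counts.loc[samples].to_numpy(dtype=float)
        present = [
            _present(row) for row in counts
        ]
        pairs = [(a, b) for a in range(len(samples))
                 for b in range(a + 1, len(samples))]
        ss_tips, ss_rc = master.spawn(2)
        rng_tips = np.random.default_rng(ss_tips)
        obs = np.array([
            _bmntd(present[a][1], present[b][1],
                   D[np.ix_(present[a][0], present[b][0])])
            for a, b in pairs
        ])
        null = np.empty((n_null, len(pairs)))
        n_pool = D.shape[0]
        for r in range(n_null):
            perm = rng_tips.permutation(n_pool)
            for q, (a, b) in enumerate(pairs):
                null[r, q] = _bmntd(
                    present[a][1], present[b][1],
                    D[np.ix_(perm[present[a][0]], perm[present[b][0]])])
        mu = null.mean(axis=0)
        sd = null.std(axis=0, ddof=1)

        rc_children = ss_rc.spawn(len(pairs))
        pool_table = CommunityTable(sub.counts)
        for q, (a, b) in enumerate(pairs):
            si, sj = samples[a], samples[b]
            if sd[q] <= 0:
                logger.warning("degenerate pair (%s, %s) excluded", si, sj)
                continue
            bnti = (obs[q] - mu[q]) / sd[q]
            bc_obs, rc = raup_crick_bray(
                pool_table, si, sj, n_null=n_null,
                seed=rc_children[q], pool_samples=samples
                if pool == "group" else None)
            pair_rows.append(dict(
                group=gname, sample_i=si, sample_j=sj,
                bmntd_obs=obs[q], null_mean=mu[q], null_sd=sd[q],
                bnti=bnti, bc_obs=bc_obs, rc_bray=rc,
                process=classify_process(bnti, rc),
            ))

    pairs_df = pd.DataFrame(pair_rows)
    summary = summarize_processes(pairs_df, meta=meta, between_col=between_col)
    return pairs_df, summary


def summarize_processes(pairs_df: pd.DataFrame,
                        meta: pd.DataFrame | None = None,
                        between_col: str | None = None) -> pd.DataFrame:
    """Per-group process fractions and the selection : dispersal ratio."""
    if pairs_df.empty:
        return pd.DataFrame(columns=["group", *PROCESSES, "n_pairs",
                                     "selection_to_dispersal"])
    df = pairs_df
    if between_col is not None:
        if meta is None or between_col not in meta.columns:
            raise ValueError(f"column {between_col!r} not in metadata")
        fac = meta[between_col]
        df = df[fac.loc[df.sample_i].to_numpy()
                != fac.loc[df.sample_j].to_numpy()]
    rows = []
    for gname, gdf in df.groupby("group"):
        frac = gdf["process"].value_counts(normalize=True)
        row = {"group": gname}
        for p in PROCESSES:
            row[p] = float(frac.get(p, 0.0))
        row["n_pairs"] = len(gdf)
        selection = row["heterogeneous_selection"] + row["homogeneous_selection"]
        dispersal = row["dispersal_limitation"] + row["homogenizing_dispersal"]
        row["selection_to_dispersal"] = (
            selection / dispersal if dispersal > 0 else np.inf)
        rows.append(row)
    return pd.DataFrame(rows)
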