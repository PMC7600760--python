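"""Biogeographic pattern statistics.

Bray–Curtis dissimilarity, principal coordinate analysis, one-way and
two-way crossed ANOSIM, SIMPER decomposition of between-group dissimilarity,
great-circle distances, distance–decay regression with Mantel significance,
and covariation of ordination axes with distance to land.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from scipy.stats import pearsonr, rankdata, spearmanr
from skbio import DistanceMatrix

from .io import CommunityTable

__all__ = [
    "OrdinationResult", "bray_curtis_matrix", "pcoa", "anosim", "simper",
    "haversine_km", "geographic_distance_matrix", "distance_decay",
    "axis_vs_distance",
]

EARTH_RADIUS_KM = 6371.0


def bray_curtis_matrix(table: CommunityTable) -> DistanceMatrix:
    """Pairwise Bray–Curtis dissimilarity between samples.

    BC(i,j) = 1 − 2·Σ_t min(x_it, x_jt) / (Σ_t x_it + Σ_t x_jt) ∈ [0, 1].
    """
    X = table.counts.to_numpy(dtype=float)
    if (X.sum(axis=1) == 0).any():
        raise ValueError("all-zero sample in Bray-Curtis computation")
    return DistanceMatrix(squareform(pdist(X, metric="braycurtis")),
                          ids=table.sample_ids)


@dataclass
class OrdinationResult:
    """Principal coordinates: samples x axes, eigenvalues, variance explained.

    ``eigenvalues`` reports the full Gower spectrum (negative values
    included); ``coordinates`` keeps only positive-eigenvalue axes and
    ``proportion_explained`` divides by the sum of positive eigenvalues.
    """

    coordinates: pd.DataFrame
    eigenvalues: np.ndarray
    proportion_explained: np.ndarray


def _gower_center(d: np.ndarray) -> np.ndarray:
    A = -0.5 * d**2
    n = d.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    return J @ A @ J


def pcoa(d: DistanceMatrix) -> OrdinationResult:
    """Principal coordinate analysis by Gower double-centering.

    Axes are ordered by decreasing eigenvalue; coordinates are eigenvectors
    scaled by the square root of their (positive) eigenvalues, so inter-point
    distances in the full coordinate space reproduce any Euclidean-embeddable
    input exactly.
    """
    n = d.shape[0]
    if n < 3:
        raise ValueError("PCoA needs at least 3 samples")
    G = _gower_center(d.data)
    eigval, eigvec = np.linalg.eigh(G)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]
    pos = eigval > max(eigval.max(), 0) * 1e-10
    coords = eigvec[:, pos] * np.sqrt(eigval[pos])
    prop = eigval[pos] / eigval[pos].sum()
    cols = [f"PC{k + 1}" for k in range(coords.shape[1])]
    return OrdinationResult(
        coordinates=pd.DataFrame(coords, index=list(d.ids), columns=cols),
        eigenvalues=eigval,
        proportion_explained=prop,
    )


def _anosim_r(ranks: np.ndarray, within: np.ndarray) -> float:
    M = ranks.size
    rw = ranks[within].mean()
    rb = ranks[~within].mean()
    return float((rb - rw) / (M / 2.0))


def anosim(d: DistanceMatrix, groups, n_perm: int = 999, seed: int = 0,
            strata=None):
    """Analysis of similarities: R statistic and permutation p-value.

    R = (mean between-group rank − mean within-group rank) / (M/2) with
    M = n(n−1)/2 ranked dissimilarities.  With ``strata`` (a second crossed
    factor), the two-way crossed statistic is the average of per-stratum
    one-way R values, and permutations shuffle group labels within strata
    only.
    """
    ids = list(d.ids)
    g = np.asarray(pd.Series(groups, index=ids).loc[ids] if isinstance(
        groups, (pd.Series, dict)) else groups)
    counts = pd.Series(g).value_counts()
    if len(counts) < 2:
        raise ValueError("ANOSIM needs at least 2 groups")
    if (counts < 2).any():
        raise ValueError(f"groups of size 1: {counts[counts < 2].index.tolist()}")
    rng = np.random.default_rng(seed)
    n = len(ids)
    iu = np.triu_indices(n, k=1)

    if strata is None:
        ranks = rankdata(d.data[iu])

        def stat(labels):
            within = labels[iu[0]] == labels[iu[1]]
            return _anosim_r(ranks, within)

        r_obs = stat(g)
        count = 0
        for _ in range(n_perm):
            count += stat(rng.permutation(g)) >= r_obs - 1e-12
        return r_obs, (count + 1.0) / (n_perm + 1.0)

    s = np.asarray(pd.Series(strata, index=ids).loc[ids] if isinstance(
        strata, (pd.Series, dict)) else strata)
    levels = pd.unique(s)
    blocks = []
    for lev in levels:
        idx = np.flatnonzero(s == lev)
        if len(pd.unique(g[idx])) < 2:
            continue
        sub = d.data[np.ix_(idx, idx)]
        siu = np.triu_indices(len(idx), k=1)
        blocks.append((idx, rankdata(sub[siu]), siu))
    if not blocks:
        raise ValueError("no stratum contains 2 groups")

    def crossed_stat(labels):
        rs = []
        for idx, ranks, siu in blocks:
            lab = labels[idx]
            within = lab[siu[0]] == lab[siu[1]]
            if within.all() or not within.any():
                continue
            rs.append(_anosim_r(ranks, within))
        return float(np.mean(rs))

    r_obs = crossed_stat(g)
    count = 0
    gp = g.copy()
    for _ in range(n_perm):
        for idx, _, _ in blocks:
            gp[idx] = rng.permutation(gp[idx])
        count += crossed_stat(gp) >= r_obs - 1e-12
    return r_obs, (count + 1.0) / (n_perm + 1.0)


def simper(table: CommunityTable, groups, group_a: str, group_b: str) -> pd.DataFrame:
    """SIMPER: per-taxon contribution to mean between-group Bray–Curtis.

    For each between-group sample pair the Bray–Curtis sum is expanded into
    per-taxon terms |x_it − x_jt| / Σ_t (x_it + x_jt); contributions are the
    means of these terms over pairs and sum exactly to the mean between-group
    dissimilarity.  Rows are sorted by decreasing contribution and carry the
    cumulative percentage.
    """
    g = pd.Series(np.asarray(groups), index=table.sample_ids)
    ia = g.index[g == group_a]
    ib = g.index[g == group_b]
    if len(ia) == 0 or len(ib) == 0:
        raise ValueError(f"empty group among ({group_a!r}, {group_b!r})")
    A = table.counts.loc[ia].to_numpy(dtype=float)
    B = table.counts.loc[ib].to_numpy(dtype=float)
    contrib = np.zeros(table.n_taxa)
    n_pairs = 0
    for u in A:
        for v in B:
            contrib += np.abs(u - v) / (u.sum() + v.sum())
            n_pairs += 1
    contrib /= n_pairs
    out = pd.DataFrame({
        "taxon_id": table.taxon_ids,
        "contribution": contrib,
    }).sort_values("contribution", ascending=False, kind="stable")
    total = contrib.sum()
    out["cumulative_pct"] = 100.0 * out["contribution"].cumsum() / total
    return out.reset_index(drop=True)


def haversine_km(lat1, lon1, lat2, lon2) -> float:
    """Great-circle distance in km (Earth radius 6371.0 km)."""
    for lat in (lat1, lat2):
        if not -90.0 <= lat <= 90.0:
            raise ValueError(f"latitude out of range: {lat}")
    for lon in (lon1, lon2):
        if not -180.0 <= lon <= 180.0:
            raise ValueError(f"longitude out of range: {lon}")
    p1, p2 = np.deg2rad(lat1), np.deg2rad(lat2)
    dphi = p2 - p1
    dlmb = np.deg2rad(lon2) - np.deg2rad(lon1)
    a = np.sin(dphi / 2) ** 2 + np.cos(p1) * np.cos(p2) * np.sin(dlmb / 2) ** 2
    return float(2 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(a)))


def geographic_distance_matrix(meta: pd.DataFrame) -> DistanceMatrix:
    """Pairwise great-circle distances from metadata latitude/longitude."""
    ids = list(meta.index)
    lat = meta["latitude"].to_numpy(dtype=float)
    lon = meta["longitude"].to_numpy(dtype=float)
    n = len(ids)
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            out[i, j] = out[j, i] = haversine_km(lat[i], lon[i], lat[j], lon[j])
    return DistanceMatrix(out, ids=ids)


def distance_decay(d: DistanceMatrix, geo: DistanceMatrix,
                   n_perm: int = 999, seed: int = 0,
                   log_distance: bool = False):
    """Distance–decay of similarity: OLS of (1 − BC) on geographic distance.

    Significance is assessed by Mantel permutation of sample labels (the
    regression slope/correlation is recomputed under joint row/column
    shuffles of the similarity matrix).  A genuine decay yields a negative
    slope.  ``log_distance`` regresses on log(km) instead of raw km.

    Returns ``(slope, intercept, r, p)``.
    """
    if list(d.ids) != list(geo.ids):
        geo = geo.filter(d.ids)
    n = d.shape[0]
    if n < 4:
        raise ValueError("distance-decay needs at least 4 samples")
    iu = np.triu_indices(n, k=1)
    x = geo.data[iu]
    if log_distance:
        if (x <= 0).any():
            raise ValueError("log-distance requires positive distances")
        x = np.log(x)
    if x.std() == 0:
        raise ValueError("zero variance in geographic distances")
    sim_mat = 1.0 - d.data
    y = sim_mat[iu]
    slope, intercept = np.polyfit(x, y, 1)
    r = float(np.corrcoef(x, y)[0, 1]) if y.std() > 0 else 0.0
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        p = rng.permutation(n)
        yp = sim_mat[np.ix_(p, p)][iu]
        rp = np.corrcoef(x, yp)[0, 1] if yp.std() > 0 else 0.0
        # one-tailed toward decay (negative correlation of similarity with km)
        count += rp <= r + 1e-12
    pval = (count + 1.0) / (n_perm + 1.0)
    return float(slope), float(intercept), r, float(pval)


def axis_vs_distance(ordination: OrdinationResult, dtl, axis: int = 1,
                     n_perm: int = 999, seed: int = 0):
    """Covariation of an ordination axis with distance to land.

    Reports Pearson and Spearman correlations of the chosen principal
    coordinate with the per-sample distance-to-land (km), a permutation
    p-value for the Pearson correlation, and the coefficients of a degree-2
    polynomial fit (axis ~ a·DTL² + b·DTL + c) capturing curvilinear
    nearshore-to-offshore trends.

    Returns a dict with keys pearson_r, spearman_rho, p, quadratic (a, b, c).
    """
    y = ordination.coordinates.iloc[:, axis - 1].to_numpy()
    x = pd.Series(dtl).loc[ordination.coordinates.index].to_numpy(dtype=float) \
        if isinstance(dtl, pd.Series) else np.asarray(dtl, dtype=float)
    if y.std() == 0 or x.std() == 0:
        raise ValueError("constant axis or constant distance-to-land")
    r = float(pearsonr(x, y)[0])
    rho = float(spearmanr(x, y)[0])
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        rp = np.corrcoef(x, rng.permutation(y))[0, 1]
        count += abs(rp) >= abs(r) - 1e-12
    pval = (count + 1.0) / (n_perm + 1.0)
    quad = np.polyfit(x, y, 2)
    return {"pearson_r": r, "spearman_rho": rho, "p": float(pval),
            "quadratic": tuple(float(c) for c in quad)}
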