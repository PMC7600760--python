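"""Environmental vs. spatial drivers of compositional variation.

Distance-based redundancy analysis (db-RDA) on principal coordinates with
Lingoes correction, Ezekiel-adjusted R², marginal permutation tests per
predictor, greedy forward selection with a double stopping rule, PCNM
spatial eigenvectors from a truncated geographic distance matrix, and
abiotic/biotic/spatial variation partitioning by inclusion–exclusion of
adjusted R² values.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.sparse.csgraph import minimum_spanning_tree
from skbio import DistanceMatrix
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

__all__ = [
    "PcnmBasis", "pcnm", "dbrda_adjusted_r2", "marginal_tests",
    "forward_selection", "variation_partition", "PartitionResult",
]

_EIG_TOL = 1e-10


@dataclass
class PcnmBasis:
    """Spatial eigenvectors: samples x k principal coordinates of the
    truncated neighbour matrix, their (positive) eigenvalues, and the
    truncation distance in km."""

    eigenvectors: pd.DataFrame
    eigenvalues: np.ndarray
    truncation: float


def pcnm(geo: DistanceMatrix, truncation: float | None = None) -> PcnmBasis:
    """Principal coordinates of neighbour matrices.

    Distances above the truncation threshold (default: the longest edge of
    the minimum spanning tree of the sites, so the neighbour graph stays
    connected) are replaced by 4x the threshold; the modified matrix is
    double-centered and eigendecomposed; axes with positive eigenvalues are
    kept as multi-scale spatial predictors.
    """
    D = geo.data.copy()
    off = D[np.triu_indices_from(D, k=1)]
    if off.max() == 0:
        raise ValueError("all sites co-located; PCNM undefined")
    if truncation is None:
        mst = minimum_spanning_tree(D).toarray()
        truncation = float(mst.max())
    D[D > truncation] = 4.0 * truncation
    np.fill_diagonal(D, 0.0)
    G = _gower(D)
    eigval, eigvec = np.linalg.eigh(G)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]
    pos = eigval > eigval.max() * _EIG_TOL
    coords = eigvec[:, pos] * np.sqrt(eigval[pos])
    cols = [f"PCNM{k + 1}" for k in range(coords.shape[1])]
    return PcnmBasis(
        eigenvectors=pd.DataFrame(coords, index=list(geo.ids), columns=cols),
        eigenvalues=eigval[pos],
        truncation=truncation,
    )


def _gower(d: np.ndarray) -> np.ndarray:
    n = d.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    return J @ (-0.5 * d**2) @ J


def _response_coords(d: DistanceMatrix) -> np.ndarray:
    """PCoA axes of the dissimilarity with Lingoes correction.

    When the Gower spectrum has negative eigenvalues, the Lingoes constant
    (the magnitude of the most negative one) is added to every non-null
    eigenvalue, making the configuration Euclidean while preserving the
    ordering of dissimilarities.
    """
    G = _gower(d.data)
    eigval, eigvec = np.linalg.eigh(G)
    if eigval.min() < -abs(eigval).max() * _EIG_TOL:
        eigval = eigval + abs(eigval.min())
    eigval = np.where(eigval > abs(eigval).max() * _EIG_TOL, eigval, 0.0)
    keep = eigval > 0
    return eigvec[:, keep] * np.sqrt(eigval[keep])


def _as_block(X) -> pd.DataFrame:
    """Coerce a predictor block to a numeric DataFrame (factors one-hot)."""
    if isinstance(X, PcnmBasis):
        return X.eigenvectors
    X = pd.DataFrame(X).copy()
    cat = X.columns[[not pd.api.types.is_numeric_dtype(X[c]) for c in X.columns]]
    if len(cat):
        X = pd.get_dummies(X, columns=list(cat), drop_first=True, dtype=float)
    return X.astype(float)


def _rank_and_redundant(Xc: np.ndarray, cols) -> tuple[int, list]:
    rank = np.linalg.matrix_rank(Xc) if Xc.size else 0
    redundant = []
    if rank < Xc.shape[1]:
        kept = np.empty((Xc.shape[0], 0))
        for j, c in enumerate(cols):
            trial = np.column_stack([kept, Xc[:, j]])
            if np.linalg.matrix_rank(trial) > kept.shape[1]:
                kept = trial
            else:
                redundant.append(c)
    return rank, redundant


def _fit_r2(Y: np.ndarray, Xc: np.ndarray) -> float:
    """Fraction of total inertia explained by the (centered) predictors.

    Uses a rank-revealing SVD projection so collinear/duplicated columns
    cannot inflate the fit numerically.
    """
    if Xc.shape[1] == 0:
        return 0.0
    U, s, _ = np.linalg.svd(Xc, full_matrices=False)
    Ur = U[:, s > s.max() * 1e-10] if s.max() > 0 else U[:, :0]
    fitted = Ur @ (Ur.T @ Y)
    return float((fitted**2).sum() / (Y**2).sum())


def _adjust(r2: float, n: int, p: int) -> float:
    if p == 0:
        return 0.0
    if n - p - 1 <= 0:
        raise ValueError("not enough residual degrees of freedom")
    return 1.0 - (1.0 - r2) * (n - 1) / (n - p - 1)


def dbrda_adjusted_r2(d: DistanceMatrix, X, n_perm: int = 999, seed: int = 0):
    """db-RDA of a dissimilarity matrix on a predictor block.

    The response is the full set of Lingoes-corrected principal coordinates;
    R² is constrained over total inertia, adjusted by Ezekiel's formula
    1 − (1 − R²)(n − 1)/(n − p − 1), and the pseudo-F is tested by permuting
    the rows of the response.

    Returns a dict: r2, adj_r2, pseudo_f, p, df.
    """
    Xdf = _as_block(X)
    if list(Xdf.index) != list(d.ids) and len(Xdf) == len(d.ids):
        Xdf = Xdf.loc[list(d.ids)] if Xdf.index.is_unique and set(
            d.ids) <= set(Xdf.index) else Xdf
    Xc = Xdf.to_numpy() - Xdf.to_numpy().mean(axis=0)
    n = len(d.ids)
    rank, redundant = _rank_and_redundant(Xc, list(Xdf.columns))
    if redundant:
        raise ValueError(f"collinear predictor block; drop columns: {redundant}")
    p = rank
    if n <= p + 1:
        raise ValueError("need n > p + 1 samples")
    Y = _response_coords(d)
    Yc = Y - Y.mean(axis=0)
    r2 = _fit_r2(Yc, Xc)
    adj = _adjust(r2, n, p)
    if p == 0:
        return {"r2": 0.0, "adj_r2": 0.0, "pseudo_f": np.nan, "p": np.nan, "df": 0}
    f_obs = (r2 / p) / ((1.0 - r2) / (n - p - 1))
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        r2p = _fit_r2(Yc[perm], Xc)
        fp = (r2p / p) / ((1.0 - r2p) / (n - p - 1))
        count += fp >= f_obs - 1e-12
    return {"r2": r2, "adj_r2": adj,
            "pseudo_f": f_obs, "p": (count + 1.0) / (n_perm + 1.0), "df": p}


def marginal_tests(d: DistanceMatrix, predictors: pd.DataFrame,
                   n_perm: int = 999, seed: int = 0) -> pd.DataFrame:
    """One db-RDA per predictor variable, each tested alone.

    Constant variables are skipped with a warning.  Raw permutation p-values
    are reported alongside Benjamini–Hochberg-corrected ones.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for col in predictors.columns:
        x = predictors[[col]]
        if _as_block(x).iloc[:, 0].std() == 0:
            logger.warning("skipping constant predictor %r", col)
            continue
        res = dbrda_adjusted_r2(d, x, n_perm=n_perm,
                                seed=int(rng.integers(2**31)))
        rows.append({"variable": col, "pseudo_f": res["pseudo_f"],
                     "p": res["p"], "r2": res["r2"], "adj_r2": res["adj_r2"]})
    out = pd.DataFrame(rows)
    if not out.empty:
        out["p_bh"] = multipletests(out["p"], method="fdr_bh")[1]
    return out


def forward_selection(d: DistanceMatrix, predictors, alpha: float = 0.05,
                      n_perm: int = 999, seed: int = 0) -> list[str]:
    """Greedy forward selection of predictors for db-RDA.

    At each step the candidate with the largest conditional R² gain is
    admitted if (1) its conditional permutation p-value is <= alpha and
    (2) the cumulative adjusted R² of the already-selected model has not
    exceeded the full-model adjusted R² (double stopping rule; applying the
    bound to the selected model rather than the trial model keeps a strong
    single driver admissible when noise candidates depress the full-model
    adjusted R²).  Candidates adding no rank (duplicates, collinear columns)
    are never admitted.  May return an empty list.
    """
    Xdf = _as_block(predictors)
    n = len(d.ids)
    Y = _response_coords(d)
    Yc = Y - Y.mean(axis=0)
    Xall = Xdf.to_numpy() - Xdf.to_numpy().mean(axis=0)
    # full model on a maximal independent column subset
    rank, redundant = _rank_and_redundant(Xall, list(Xdf.columns))
    indep = [c for c in Xdf.columns if c not in redundant]
    full_cols = [Xdf.columns.get_loc(c) for c in indep]
    if n <= rank + 1:
        raise ValueError("need n > p + 1 for the full model")
    full_adj = _adjust(_fit_r2(Yc, Xall[:, full_cols]), n, rank)

    rng = np.random.default_rng(seed)
    selected: list[str] = []
    sel_idx: list[int] = []
    r2_sel = 0.0
    while True:
        best = None
        for j, col in enumerate(Xdf.columns):
            if col in selected:
                continue
            trial = Xall[:, sel_idx + [j]]
            if np.linalg.matrix_rank(trial) <= len(sel_idx):
                continue  # zero conditional gain (duplicate/collinear)
            gain = _fit_r2(Yc, trial) - r2_sel
            if best is None or gain > best[0]:
                best = (gain, j, col)
        if best is None:
            break
        gain, j, col = best
        p_new = len(sel_idx) + 1
        r2_new = r2_sel + gain
        if _adjust(r2_sel, n, len(sel_idx)) > full_adj + 1e-9:
            break
        f_obs = (gain / 1.0) / ((1.0 - r2_new) / (n - p_new - 1))
        # conditional test: permute residuals of Y on the selected block
        if sel_idx:
            Q, _ = np.linalg.qr(Xall[:, sel_idx])
            Yres = Yc - Q @ (Q.T @ Yc)
        else:
            Yres = Yc
        count = 0
        for _ in range(n_perm):
            perm = rng.permutation(n)
            Yp = (Q @ (Q.T @ Yc) if sel_idx else 0) + Yres[perm]
            r2p = _fit_r2(Yp - Yp.mean(axis=0) if sel_idx else Yp,
                          Xall[:, sel_idx + [j]])
            r2p_old = _fit_r2(Yp - Yp.mean(axis=0) if sel_idx else Yp,
                              Xall[:, sel_idx]) if sel_idx else 0.0
            gp = r2p - r2p_old
            fp = gp / ((1.0 - r2p) / (n - p_new - 1))
            count += fp >= f_obs - 1e-12
        pval = (count + 1.0) / (n_perm + 1.0)
        if pval > alpha:
            break
        selected.append(col)
        sel_idx.append(j)
        r2_sel = r2_new
    return selected


@dataclass
class PartitionResult:
    """Adjusted-R² variation partition over abiotic (A), biotic (B) and
    spatial (S) blocks: three pure fractions, three pairwise-shared, one
    three-way shared, and the unexplained remainder.  Adjusted fractions may
    be negative; they are reported as-is (display layers may blank them)."""

    fractions: dict

    def as_series(self) -> pd.Series:
        return pd.Series(self.fractions)

    @property
    def total(self) -> float:
        return float(sum(self.fractions.values()))


def variation_partition(d: DistanceMatrix, abiotic=None, biotic=None,
                        spatial=None) -> PartitionResult:
    """Partition compositional variation among three predictor blocks.

    Fits the 7 possible db-RDA models (each block alone, each pair, all
    three), adjusts every R², and solves for the 7 fractions by
    inclusion–exclusion; unexplained = 1 − adjR²(all blocks).  Empty blocks
    contribute nothing.  Blocks are expected to be pre-reduced by forward
    selection.
    """
    blocks = {"abiotic": abiotic, "biotic": biotic, "spatial": spatial}
    mats = {}
    n = len(d.ids)
    for name, b in blocks.items():
        if b is None:
            mats[name] = np.empty((n, 0))
        else:
            M = _as_block(b).to_numpy()
            mats[name] = M - M.mean(axis=0)
    Y = _response_coords(d)
    Yc = Y - Y.mean(axis=0)

    def adj(*names):
        X = np.column_stack([mats[nm] for nm in names]) if names else np.empty((n, 0))
        p = np.linalg.matrix_rank(X) if X.size else 0
        return _adjust(_fit_r2(Yc, X), n, p)

    A, B, C = adj("abiotic"), adj("biotic"), adj("spatial")
    AB, AC, BC = adj("abiotic", "biotic"), adj("abiotic", "spatial"), adj("biotic", "spatial")
    ABC = adj("abiotic", "biotic", "spatial")
    fr = {
        "abiotic_pure": ABC - BC,
        "biotic_pure": ABC - AC,
        "spatial_pure": ABC - AB,
        "abiotic_biotic_shared": AC + BC - C - ABC,
        "abiotic_spatial_shared": AB + BC - B - ABC,
        "biotic_spatial_shared": AB + AC - A - ABC,
        "three_way_shared": A + B + C - AB - AC - BC + ABC,
        "unexplained": 1.0 - ABC,
    }
    return PartitionResult(fractions=fr)
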