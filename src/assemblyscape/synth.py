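"""Synthetic metacommunities with known assembly regimes.

Generates the (counts, tree, metadata) triple under one of five scenario
presets — heterogeneous selection, homogeneous selection, dispersal
limitation, homogenizing dispersal, undominated — so every inference stage
of the pipeline can be exercised against ground truth.

The generative model: a Yule tree carries taxon niche optima evolved by
Brownian motion, optionally with the variance confined to branches deeper
than a conservatism depth so that recent clades share their niche (signal
concentrated at short phylogenetic distances — the regime the null-model
framework presupposes).  A regional log-normal abundance pool is filtered
per site by a Gaussian niche kernel around the site's environmental value;
per-site Wright–Fisher-like drift and a migration parameter produce the
stochastic regimes; per-sample recruitment thinning and abundance noise
produce within-niche turnover between replicates; each sample is a
multinomial draw of fixed read depth.  A study may span several seasons on
the same phylogeny, each season with its own niche-trait realization and
regional pool.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from skbio import TreeNode

from .io import CommunityTable

logger = logging.getLogger(__name__)

SCENARIOS = (
    "heterogeneous_selection",
    "homogeneous_selection",
    "dispersal_limitation",
    "homogenizing_dispersal",
    "undominated",
)

#: great-circle km between adjacent synthetic stations (nearshore -> offshore)
SITE_SPACING_KM = 15.0
EARTH_RADIUS_KM = 6371.0
_BASE_LAT = 38.5
_BASE_LON = 118.0


@dataclass
class ScenarioConfig:
    """Parameters of one simulated metacommunity study.

    sigma_filter
        Width (environment units) of the Gaussian niche filter.
    migration
        In [0, 1]; mixes the regional pool back into each site's pool every
        drift generation (1 = full homogenization).
    drift_generations / drift_pool_size
        Successive multinomial resamples of the site pool and their size
        (Wright–Fisher-like drift; more generations = stronger divergence).
    per_sample_drift
        Additional drift generations applied independently per sample.
    bm_rate
        Trait variance per unit branch length on the depth-1 tree, so niche
        optima have unit variance at bm_rate = 1.
    niche_conservatism
        In (0, 1]; relative tree depth after which the niche trait stops
        evolving.  1.0 is plain Brownian motion; smaller values make recent
        clades share one optimum (niche conservatism at short distances).
    niche_lineages
        If set, overrides ``niche_conservatism`` per tree: the conservatism
        depth is placed where the tree has exactly this many ancestral
        lineages, fixing the number (and so the typical size) of
        niche-conserved clades independently of the Yule realization.
    niche_breadth_quantile
        If set (0, 1), only that fraction of taxa — those whose optima best
        match the site environment — are admitted to the niche (competitive
        saturation); the Gaussian kernel still weights the admitted taxa.
    occupancy
        Per-sample probability that a niche member recruits at all
        (recruitment limitation; drives presence turnover among replicates).
    abund_sd
        Log-normal sigma of per-sample abundance noise.
    pool_coupling
        Exponent linking within-niche sampling weights to regional pool
        abundances (1 = proportional, 0 = locally fitness-determined).
    background
        Fraction of each sample's reads drawn from the unfiltered regional
        pool (mass effects; seeds rare out-of-niche taxa).
    env_noise
        Standard deviation of the sample-level environmental fluctuation
        around the site mean; the niche filter acts on the realized
        per-sample value, which the metadata also reports.
    n_seasons
        Number of seasonal datasets sharing one phylogeny; each season gets
        an independent trait realization and regional pool.
    """

    scenario: str = "heterogeneous_selection"
    n_taxa: int = 300
    n_sites: int = 5
    n_reps: int = 5
    n_seasons: int = 1
    depth: int = 2000
    env_values: list[float] | None = None
    sigma_filter: float = 0.5
    migration: float = 0.0
    drift_generations: int = 0
    drift_pool_size: int = 2000
    per_sample_drift: int = 0
    bm_rate: float = 1.0
    niche_conservatism: float = 1.0
    niche_lineages: int | None = None
    niche_breadth_quantile: float | None = None
    occupancy: float = 1.0
    abund_sd: float = 0.0
    pool_coupling: float = 1.0
    background: float = 0.0
    env_noise: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.scenario not in SCENARIOS:
            raise ValueError(f"unknown scenario {self.scenario!r}")
        if self.depth < 100:
            raise ValueError("depth must be >= 100")
        if self.sigma_filter <= 0:
            raise ValueError("sigma_filter must be > 0")
        if self.n_sites < 2:
            raise ValueError("n_sites must be >= 2")
        if not 0.0 <= self.migration <= 1.0:
            raise ValueError("migration must be in [0, 1]")
        if not 0.0 < self.niche_conservatism <= 1.0:
            raise ValueError("niche_conservatism must be in (0, 1]")
        if not 0.0 < self.occupancy <= 1.0:
            raise ValueError("occupancy must be in (0, 1]")
        if not 0.0 <= self.background < 1.0:
            raise ValueError("background must be in [0, 1)")
        if self.env_values is not None and len(self.env_values) != self.n_sites:
            raise ValueError("env_values length must equal n_sites")


def preset(scenario: str, **overrides) -> ScenarioConfig:
    """Scenario preset mapping each assembly regime to generator settings.

    ``heterogeneous_selection``: sites along an environmental gradient with
    a narrow niche filter.  ``homogeneous_selection``: one four-season study
    under identical environments everywhere, with strong niche conservatism,
    competitive niche saturation and recruitment-limited replicates — the
    regime in which communities are consistently clustered subsets of the
    regional pool.  ``dispersal_limitation``: no filtering, isolated
    per-site drift.  ``homogenizing_dispersal``: no filtering, one fully
    mixed pool.  ``undominated``: weak filtering, partial mixing, mild
    drift.
    """
    base = dict(
        heterogeneous_selection=dict(
            sigma_filter=0.5, migration=0.0, drift_generations=0),
        homogeneous_selection=dict(
            sigma_filter=0.35, migration=0.0, drift_generations=0,
            niche_lineages=32, niche_breadth_quantile=0.35,
            occupancy=0.45, abund_sd=0.2, pool_coupling=0.0,
            background=0.005, env_noise=0.0, n_seasons=4),
        dispersal_limitation=dict(
            sigma_filter=1e6, migration=0.0, drift_generations=50),
        homogenizing_dispersal=dict(
            sigma_filter=1e6, migration=1.0, drift_generations=0),
        undominated=dict(
            sigma_filter=4.0, migration=0.5, drift_generations=5,
            per_sample_drift=3, drift_pool_size=20000, background=0.01),
    )[scenario]
    return ScenarioConfig(scenario=scenario, **{**base, **overrides})


def simulate_tree(n_taxa: int, seed: int) -> TreeNode:
    """Pure-birth (Yule) tree with ``n_taxa`` tips, rescaled to depth 1.

    Forward simulation at unit speciation rate; after the last split every
    extant lineage is extended by one further exponential waiting time so
    terminal branches are non-degenerate, then all root-to-tip paths are
    rescaled to exactly 1.0 (ultrametric).
    """
    if n_taxa < 2:
        raise ValueError("n_taxa must be >= 2")
    rng = np.random.default_rng(seed)
    root = TreeNode(name=None, length=0.0)
    active = []
    birth = {}
    for _ in range(2):  # the process starts from the root's two lineages
        child = TreeNode(length=0.0)
        root.append(child)
        birth[id(child)] = 0.0
        active.append(child)
    t = 0.0
    while len(active) < n_taxa:
        t += rng.exponential(1.0 / len(active))
        node = active.pop(rng.integers(len(active)))
        node.length = t - birth[id(node)]
        for _ in range(2):
            child = TreeNode(length=0.0)
            node.append(child)
            birth[id(child)] = t
            active.append(child)
    t += rng.exponential(1.0 / len(active))
    for i, node in enumerate(active):
        node.length = t - birth[id(node)]
        node.name = f"t{i + 1}"
    for node in root.traverse(include_self=False):
        node.length = node.length / t
    root.length = 0.0
    return root


def evolve_optima(tree: TreeNode, bm_rate: float, seed: int,
                  conservatism: float = 1.0,
                  tip_noise: float = 0.0) -> pd.Series:
    """Niche optima evolved by Brownian motion from a root value of 0.

    The increment on a branch of length L has variance ``bm_rate * L``;
    rate 0 gives all-zero traits.  With ``conservatism`` c < 1, variance
    accumulates only on the portion of each branch deeper than relative
    depth c (rescaled so tip variance stays ``bm_rate``): clades younger
    than c inherit a common optimum, i.e. the niche is conserved across
    short phylogenetic distances.  ``tip_noise`` adds independent Gaussian
    noise to each tip.  Returns a Series indexed by tip name.
    """
    if bm_rate < 0:
        raise ValueError("bm_rate must be >= 0")
    if not 0.0 < conservatism <= 1.0:
        raise ValueError("conservatism must be in (0, 1]")
    rng = np.random.default_rng(seed)
    c = conservatism
    value = {id(tree): 0.0}
    depth = {id(tree): 0.0}
    out = {}
    for node in tree.preorder(include_self=False):
        d0 = depth[id(node.parent)]
        d1 = d0 + (node.length or 0.0)
        depth[id(node)] = d1
        L = (min(d1, c) - min(d0, c)) / c
        v = value[id(node.parent)] + rng.normal(0.0, np.sqrt(bm_rate * L))
        value[id(node)] = v
        if node.is_tip():
            out[node.name] = v + (rng.normal(0.0, tip_noise) if tip_noise else 0.0)
    return pd.Series(out, name="optimum")


def lineage_depth(tree: TreeNode, n_lineages: int) -> float:
    """Relative depth at which the tree has exactly ``n_lineages`` lineages.

    Returns a value just below the (n_lineages − 1)-th internal split, so a
    trait conserved below this depth partitions the tips into
    ``n_lineages`` clades; 1.0 when the tree has fewer splits.
    """
    depth = {id(tree): 0.0}
    starts = []
    for node in tree.preorder(include_self=False):
        depth[id(node)] = depth[id(node.parent)] + (node.length or 0.0)
        if not node.is_tip():
            starts.append(depth[id(node)])
    starts.sort()
    if n_lineages - 2 >= len(starts):
        return 1.0
    return min(starts[n_lineages - 2] + 1e-9, 1.0)


def _drift(pool: np.ndarray, generations: int, size: int,
           migration: float, regional: np.ndarray,
           rng: np.random.Generator) -> np.ndarray:
    p = pool.copy()
    for _ in range(generations):
        if migration > 0:
            p = (1.0 - migration) * p + migration * regional
        p = rng.multinomial(size, p / p.sum()) / size
    return p


def simulate_metacommunity(config: ScenarioConfig):
    """Generate one (CommunityTable, TreeNode, metadata DataFrame) triple.

    All seasons share one phylogeny.  The metadata carries season, site,
    coordinates along a shore-to-offshore transect (adjacent stations
    ~15 km apart), distance-to-land in km, the latent environmental axis
    ``env`` and three correlated measured-variable columns (temperature,
    salinity, DIN) plus an uninformative noise column.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    tree = simulate_tree(cfg.n_taxa, int(rng.integers(2**31)))
    taxa = [t.name for t in tree.tips()]
    conservatism = cfg.niche_conservatism
    if cfg.niche_lineages is not None:
        conservatism = lineage_depth(tree, cfg.niche_lineages)

    env = cfg.env_values
    if env is None:
        if cfg.scenario == "heterogeneous_selection":
            env = np.linspace(-2.0, 2.0, cfg.n_sites)
        else:
            env = np.zeros(cfg.n_sites)
    env = np.asarray(env, dtype=float)
    if cfg.scenario == "heterogeneous_selection" and np.ptp(env) == 0:
        logger.warning(
            "heterogeneous_selection with identical environmental values "
            "cannot generate between-site selection")

    rows, sample_ids, meta_rows = [], [], []
    for season_i in range(cfg.n_seasons):
        season = f"S{season_i + 1}"
        optima = evolve_optima(
            tree, cfg.bm_rate, int(rng.integers(2**31)),
            conservatism=conservatism,
            tip_noise=0.02 if conservatism < 1.0 else 0.0)
        opt = optima.loc[taxa].to_numpy()
        regional = rng.lognormal(0.0, 1.0, cfg.n_taxa)
        regional /= regional.sum()
        # secondary site-level axis (e.g. riverine salinity) the bacteria
        # do not respond to; keeps measured variables from being collinear
        env2 = rng.normal(0.0, 1.0, cfg.n_sites)

        for s in range(cfg.n_sites):
            site_drift = None
            if cfg.drift_generations > 0:
                base = np.power(regional, cfg.pool_coupling) * np.exp(
                    -((opt - env[s]) ** 2) / (2.0 * cfg.sigma_filter**2))
                site_drift = _drift(base / base.sum(), cfg.drift_generations,
                                    cfg.drift_pool_size, cfg.migration,
                                    regional, rng)
            lat, lon, dtl = _station_position(s)
            for r in range(cfg.n_reps):
                env_s = env[s] + rng.normal(0.0, cfg.env_noise)
                if site_drift is not None:
                    w = site_drift.copy()
                else:
                    kernel = np.exp(
                        -((opt - env_s) ** 2) / (2.0 * cfg.sigma_filter**2))
                    if cfg.niche_breadth_quantile is not None:
                        thr = np.quantile(
                            kernel, 1.0 - cfg.niche_breadth_quantile)
                        kernel = np.where(kernel >= thr, kernel, 0.0)
                    w = np.power(regional, cfg.pool_coupling) * kernel
                    if w.sum() <= 0:
                        raise ValueError(
                            f"niche filter removed every taxon at site {s + 1}")
                if cfg.occupancy < 1.0:
                    w = w * (rng.random(cfg.n_taxa) < cfg.occupancy)
                if cfg.abund_sd > 0:
                    w = w * rng.lognormal(0.0, cfg.abund_sd, cfg.n_taxa)
                if cfg.per_sample_drift > 0 and w.sum() > 0:
                    w = _drift(w / w.sum(), cfg.per_sample_drift,
                               cfg.drift_pool_size, 0.0, regional, rng)
                if w.sum() == 0:
                    w = regional.copy()
                w = w / w.sum()
                if cfg.background > 0:
                    w = (1.0 - cfg.background) * w + cfg.background * regional
                rows.append(rng.multinomial(cfg.depth, w / w.sum()))
                sid = f"{season}_site{s + 1}_r{r + 1}"
                sample_ids.append(sid)
                meta_rows.append(dict(
                    sample_id=sid, season=season, site=f"site{s + 1}",
                    latitude=lat, longitude=lon, distance_to_land=dtl,
                    env=env_s,
                    temperature=20.0 + 2.0 * env_s + rng.normal(0, 0.1),
                    salinity=31.0 - 0.8 * env_s + 0.8 * env2[s]
                        + rng.normal(0, 0.1),
                    DIN=0.40 + 0.15 * env_s + 0.20 * env_s**2
                        + rng.normal(0, 0.01),
                    noise=rng.normal(0, 1),
                ))

    table = CommunityTable(
        pd.DataFrame(np.array(rows, dtype=np.int64),
                     index=sample_ids, columns=taxa))
    meta = pd.DataFrame(meta_rows).set_index("sample_id")
    return table, tree, meta


def _station_position(site_index: int):
    """Stations on a line of latitude, spaced SITE_SPACING_KM apart."""
    km_per_deg_lon = (np.pi / 180.0) * EARTH_RADIUS_KM * np.cos(
        np.deg2rad(_BASE_LAT))
    lon = _BASE_LON + site_index * SITE_SPACING_KM / km_per_deg_lon
    dtl = 5.0 + site_index * SITE_SPACING_KM
    return _BASE_LAT, lon, dtl


def simulate_biotic_block(meta: pd.DataFrame, n_vars: int = 4,
                          seed: int = 0) -> pd.DataFrame:
    """A generic biotic predictor block (phytoplankton-like) tracking env.

    Columns respond linearly to the latent environmental axis with
    independent noise, emulating phytoplankton group abundances that covary
    with the same gradient the bacteria respond to.
    """
    rng = np.random.default_rng(seed)
    env = meta["env"].to_numpy()
    cols = {}
    for j in range(n_vars):
        beta = rng.normal(0, 1)
        cols[f"phyto{j + 1}"] = beta * env + rng.normal(0, 0.5, len(env))
    return pd.DataFrame(cols, index=meta.index)
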