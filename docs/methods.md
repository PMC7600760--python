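# Methods

## The inference framework

The package quantifies, for every pair of communities, the balance of
deterministic and stochastic assembly with the standard two-step null-model
procedure.  Step one compares observed phylogenetic turnover (abundance-
weighted βMNTD) with a tip-shuffle null: because nearest-taxon distances
are only ecologically meaningful when close relatives have similar niches,
the framework's prerequisite — phylogenetic signal in niche differences at
short phylogenetic distances — is tested first with a Mantel correlogram.
Step two ranks observed Bray–Curtis dissimilarity within a
richness/abundance-preserving random-assembly null.  The joint thresholds
(|βNTI| > 2 for selection; |RC_bray| > 0.95 for dispersal processes;
otherwise undominated) use strict inequalities; boundary values fall on the
stochastic/undominated side.

### βNTI nulls

Patristic distances are computed once per taxon pool and every null
replicate is a label permutation of that matrix (identical to re-traversing
a relabelled tree, verified against a literal reimplementation and against
`picante::comdistnt` + `taxaShuffle` during development).  Within
`quantify_processes` one permutation per replicate is shared by all pairs
of a group — the natural reading of "shuffle taxa on the tree, then
re-evaluate" — while the standalone `bnti_pair` draws its own stream.  The
null taxon pool defaults to the taxa present in the analysis group
(`pool="group"`), since process fractions are reported per group and a
group's species pool is the ecologically relevant universe; `pool="global"`
is available.  Pairs whose null distribution is degenerate (σ = 0, e.g.
identical membership or a star phylogeny) are excluded and logged.

### RC_bray null

Each replicate rebuilds both communities: the sample's observed richness is
drawn without replacement with probability ∝ occupancy across the pool
samples; each drawn taxon receives one read and the remaining reads are
distributed multinomially ∝ pool mean relative abundance.  Ties in the rank
count with weight ½ and Bray–Curtis equality is judged at 1e−12.

### Statistical conventions

- Niche optima are z-standardized per variable (population SD) before the
  Euclidean niche distance; environmental variables have incommensurable
  units and unstandardized distances would be dominated by the
  largest-scaled one.
- Correlogram distance classes partition the patristic range, Sturges rule
  on the pair count by default; the per-class statistic is the Mantel
  correlation with the within-class indicator, sign-flipped so positive
  values mean positive autocorrelation; plain Holm step-down across
  testable classes; two-sided permutation p-values with the (count+1)/(B+1)
  estimator.
- PCoA is a Gower double-centering eigendecomposition; axes with negative
  eigenvalues are reported in the spectrum but excluded from coordinates,
  and explained proportions are over the positive part.  db-RDA responses
  use the Lingoes correction instead, so the full configuration is
  Euclidean and R² is well defined; Ezekiel's adjustment
  1 − (1 − R²)(n − 1)/(n − p − 1) with p the block rank.
- ANOSIM: R = (mean between-rank − mean within-rank)/(M/2).  The two-way
  crossed variant averages per-stratum one-way statistics and restricts
  permutations within strata.
- Distance decay regresses similarity (1 − BC) on raw km by OLS
  (a log-distance flag exists); significance is a one-tailed (toward decay)
  Mantel permutation of sample labels.
- PCNM: distances beyond the truncation (default: longest MST edge) are
  replaced by 4× truncation; positive-eigenvalue principal coordinates form
  the spatial block.
- Forward selection uses the double stopping rule: a candidate needs
  conditional permutation p ≤ α, and selection stops once the cumulative
  adjusted R² of the already-selected model exceeds the full-model adjusted
  R².  Applying the bound to the selected rather than the trial model keeps
  a strong single driver admissible when noise candidates depress the
  full-model adjusted R² — with the textbook trial-model bound, a lone true
  driver plus noise candidates yields an empty selection.
- Variation partitioning solves the seven fractions by inclusion–exclusion
  of the seven fitted models' adjusted R²; negative adjusted fractions are
  reported as-is (display layers may blank them); unexplained =
  1 − adjR²(all blocks).

## The synthetic metacommunity generator

The generator emulates the post-rarefaction structure of a coastal
amplicon survey: a handful of stations along a shore-to-offshore transect
(15 km spacing, distance-to-land recorded per station), several replicate
water samples per station, optionally several seasons sharing one
phylogeny, fixed per-sample read depth, and measured environmental
variables (temperature, salinity, DIN) responding to a latent gradient
with different functional forms — temperature linearly, salinity partly
through an independent second site axis, DIN with curvature — plus a pure
noise column.  Communities respond to the *sample-level* realized
environment (site mean + local fluctuation, `env_noise`), which is what
the metadata records.

Mechanisms, each switched by scenario presets:

- **Niche filtering**: per-sample taxon weights ∝ regional abundance^κ ×
  exp(−(optimum − env)²/2σ²).  Optima evolve by Brownian motion (rate 1 on
  the depth-1 Yule tree) — optionally with the variance confined to
  branches deeper than a conservatism depth, so recent clades share a
  niche.  This is exactly the regime the correlogram prerequisite
  describes, and it is what makes homogeneous selection detectable: βNTI
  < −2 requires communities to be phylogenetically clustered subsets of a
  broader pool, which plain Brownian traits at these tree sizes do not
  produce (their selected sets are phylogenetically diffuse).  The
  conservatism depth can be pinned per tree to a fixed number of ancestral
  lineages (`niche_lineages`), which stabilizes clade sizes across Yule
  realizations.
- **Competitive saturation** (`niche_breadth_quantile`): only the
  best-matched fraction of taxa is admitted to the niche.
- **Recruitment limitation and local abundance noise** (`occupancy`,
  `abund_sd`, `pool_coupling`): replicate samples draw overlapping but
  distinct subsets of the niche with fitness-determined rather than
  regional-pool-determined abundances; without this within-niche turnover
  replicate communities are multinomial copies and no between-sample
  process signal exists at all.
- **Drift** (`drift_generations`, `drift_pool_size`): repeated multinomial
  resampling of site pools (Wright–Fisher-like); `migration` mixes the
  regional pool back in each generation.
- **Mass effects** (`background`): a small read fraction from the
  unfiltered regional pool seeds rare out-of-niche taxa, keeping the
  detected taxon pool broader than the niche.

Preset regimes: heterogeneous selection (gradient ±2 SD, σ = 0.5, plain
Brownian optima); homogeneous selection (identical environments, 4-season
study, 32 niche lineages, 35% niche breadth, occupancy 0.45); dispersal
limitation (no filtering, 50 generations of isolated site drift);
homogenizing dispersal (no filtering, one fully mixed pool); undominated
(weak filter σ = 4, partial migration, mild per-sample drift).  The
regional pool is log-normal (meanlog 0, sdlog 1).

Default problem sizes (300 taxa, 5 sites × 5 replicates, depth 2000; the
validation suites use 200 taxa and depth 2000 with 299 null replicates)
are scaled-down analogues of a real survey's ~10⁴-taxon, ~12,000-read
tables; they were chosen so that each regime's signature is recoverable at
these sizes.  What the generator does **not** emulate: sequencing error
and chimeras, taxon-specific read-length/copy-number biases, temporal
autocorrelation between seasons, multi-dimensional niche axes (one latent
axis; the measured variables are transformations of it), and realistic
taxonomies.  Passing recovery tests therefore demonstrate correctness of
the inference machinery under the stated generative assumptions, not
performance on any particular real dataset.

## Numerical and degenerate-input policy

Rarefaction is multivariate-hypergeometric (without replacement), so
rarefied counts never exceed the originals; samples below depth error out
unless explicitly dropped.  All-zero samples, empty communities, constant
predictors, co-located sites and rank-deficient predictor blocks raise
errors naming the offender (constant predictors in `marginal_tests` are
skipped with a warning; rank added by a candidate is checked in forward
selection so duplicates are simply never admitted).  Fitted projections
use rank-revealing SVD so collinearity cannot inflate R² numerically.
Master seeds spawn per-stage child streams (recorded in the run manifest),
so re-running one stage leaves the others' results unchanged and results
are independent of evaluation order.

## Pipeline behaviour

`run_all` refuses to run the assembly stage when no short-distance
correlogram class is significantly positive (the prerequisite), unless
forced; "short-distance" is operationalized as the first half of the
testable classes.  Stage failures abort with a stage-named error and
rename partial outputs with a `.partial` suffix.  Note that a permutation
test with B replicates cannot produce p < 1/(B+1); with ~10 distance
classes, Holm-corrected significance at α = 0.05 needs B ≥ ~400, so the
pipeline default (999) should not be lowered below that when the
prerequisite gate matters.

## Known limitations

βNTI loses calibration when sample richness approaches the pool size (the
null's nearest-taxon distances collapse), and fully mixed high-richness
communities can show inflated |βNTI| on some tree realizations.  The
homogeneous-selection regime is intrinsically the hardest to recover at
200-taxon scale; its preset aggregates four seasonal datasets and still
recovers the modal process in roughly nine out of ten simulated studies
rather than always.  RC_bray inherits the usual sensitivity of the
Raup–Crick construction to the choice of taxon pool.  The two-way crossed
ANOSIM follows the rank-average-within-strata construction; other software
may differ in detail.
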