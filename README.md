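# assemblyscape

Null-model inference of microbial community assembly processes and the
biogeographic pattern statistics that usually accompany it, for
sample × OTU count tables with a phylogeny and environmental metadata —
the typical output of an amplicon survey across sites and seasons.

## What it computes

**Community assembly (the core).** For every pair of communities the
package runs the two-step null-model classification:

1. **βMNTD / βNTI.** The abundance-weighted β-mean nearest taxon distance

   βMNTD(i,j) = ½ [ Σ_{a∈i} f_a · min_{b∈j} d(a,b) + Σ_{b∈j} f_b · min_{a∈i} d(a,b) ]

   (f = relative abundance, d = patristic distance) is compared with a null
   distribution obtained by shuffling taxa across the tips of the taxon-pool
   phylogeny; the standardized effect size is the β-nearest taxon index,
   βNTI = (βMNTD_obs − μ_null)/σ_null.  βNTI > +2 indicates **heterogeneous
   selection**, βNTI < −2 **homogeneous selection**.
2. **RC_bray.** For the remaining (|βNTI| < 2) pairs, the modified
   Raup–Crick metric ranks the observed Bray–Curtis dissimilarity within a
   null that reassembles both communities preserving their richness and
   read totals, with membership ∝ pool occupancy and reads ∝ pool mean
   relative abundance; rescaled to [−1, 1].  RC_bray > +0.95 indicates
   **dispersal limitation**, RC_bray < −0.95 **homogenizing dispersal**,
   |RC_bray| < 0.95 **undominated** turnover.

Process fractions are aggregated per group (e.g. per season), with the
selection : dispersal ratio.

**Prerequisite check.** βNTI is only interpretable when niche differences
carry phylogenetic signal at short phylogenetic distances.  The package
estimates per-taxon niche optima (abundance-weighted means of environmental
variables), computes between-taxon niche distances, and runs a Mantel
correlogram against patristic distance with permutation tests and Holm
correction across distance classes.

**Biogeography.** Bray–Curtis dissimilarity, PCoA, one-way and two-way
crossed ANOSIM, SIMPER decomposition, great-circle distances,
distance–decay regression with Mantel significance, and
ordination-axis-vs-distance-to-land correlation with a quadratic fit.

**Drivers.** Distance-based RDA with Lingoes correction and Ezekiel
adjusted R², marginal permutation tests per predictor, forward selection
with a double stopping rule, PCNM spatial eigenvectors, and
abiotic/biotic/spatial variation partitioning by inclusion–exclusion.

**Synthetic metacommunities.** A generator produces (counts, tree,
metadata) triples under five ground-truth regimes — heterogeneous
selection, homogeneous selection, dispersal limitation, homogenizing
dispersal, undominated — so every inference stage can be validated by
parameter recovery.

## Worked example

```python
import assemblyscape as asc

cfg = asc.preset("heterogeneous_selection", n_taxa=200, n_sites=2, n_reps=5,
                 depth=2000, env_values=[-2.0, 2.0], seed=1)
table, tree, meta = asc.simulate_metacommunity(cfg)
pairs, summary = asc.quantify_processes(table, tree, meta, n_null=299, seed=2)
print(summary.to_string(index=False))
```

prints

```
group  heterogeneous_selection  homogeneous_selection  dispersal_limitation  homogenizing_dispersal  undominated  n_pairs  selection_to_dispersal
  all                 0.644444                    0.0                   0.0                0.355556          0.0       45                  1.8125
```

64% of the 45 sample pairs are classified as heterogeneous selection —
the between-site pairs, whose communities were filtered toward opposite
ends of the environmental gradient — while the within-site replicate pairs
(more similar than the Raup–Crick null expects) appear as homogenizing
dispersal; selection outweighs dispersal-related processes 1.8 : 1.

More examples, one per capability, are in `examples/` (phylogenetic-signal
check, distance decay + ANOSIM + SIMPER, variation partitioning, and the
full per-group pipeline).  A thin CLI mirrors the stages:
`assemblyscape simulate|signal|assembly|patterns|partition|run-all`.

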