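"""Simulate a selection-driven metacommunity and classify assembly processes.

Builds a two-site study with strongly different environments and a narrow
niche filter, then runs the two-step null-model classification (βNTI, then
RC_bray) over every sample pair.
"""

import assemblyscape as asc

cfg = asc.preset("heterogeneous_selection", n_taxa=200, n_sites=2, n_reps=5,
                 depth=2000, env_values=[-2.0, 2.0], seed=1)
table, tree, meta = asc.simulate_metacommunity(cfg)
print(f"simulated {table.n_samples} samples x {table.n_taxa} taxa "
      f"at depth {cfg.depth}")

pairs, summary = asc.quantify_processes(table, tree, meta, n_null=299, seed=2)
print("\nper-pair head:")
print(pairs[["sample_i", "sample_j", "bnti", "rc_bray", "process"]]
      .head(5).to_string(index=False))
print("\nprocess fractions (should be dominated by heterogeneous selection,")
print("the regime that generated the data):")
print(summary.to_string(index=False))
# The fractions sum to 1 over the five processes; selection_to_dispersal is
# the ratio of deterministic (|βNTI| > 2) to dispersal-dominated pairs.
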