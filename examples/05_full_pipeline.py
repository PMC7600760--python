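"""Run the full per-group pipeline end to end and inspect the bundle.

Writes, for each group (here one season): the signal correlogram, per-pair
assembly classifications, process fractions, ordination, ANOSIM, SIMPER,
distance decay, the variation partition, and a YAML manifest with the seeds
used by each stage.
"""

from pathlib import Path

import assemblyscape as asc
from assemblyscape.pipeline import RunConfig, run_all

cfg = asc.preset("heterogeneous_selection", n_taxa=150, n_sites=3, n_reps=4,
                 depth=1500, seed=13)
dataset = asc.simulate_metacommunity(cfg)

out = Path("scratch/pipeline_demo")
results = run_all(
    RunConfig(out_dir=str(out), group_col="season",
              env_cols=["temperature", "salinity", "DIN"],
              n_null=299, n_perm=499, seed=14),
    dataset=dataset)

for group, res in results.items():
    print(f"[{group}] signal prerequisite met: {res['signal_ok']}")
    print(res["summary"].to_string(index=False))
    slope, _, _, p = res["distance_decay"]
    print(f"distance-decay slope {slope:.3e} (p = {p:.4f})")
    print(f"outputs in {out / group}: "
          f"{sorted(p.name for p in (out / group).glob('*'))}")
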