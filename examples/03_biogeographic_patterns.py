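"""Biogeographic pattern statistics on a spatially structured community.

Under dispersal limitation, community similarity decays with geographic
distance; ANOSIM tests site-level separation and SIMPER names the taxa that
drive it; PCoA axes can be related to the distance-to-land gradient.
"""

import assemblyscape as asc

cfg = asc.preset("dispersal_limitation", n_taxa=200, n_sites=5, n_reps=3,
                 depth=2000, seed=5)
table, tree, meta = asc.simulate_metacommunity(cfg)

bc = asc.bray_curtis_matrix(table)
geo = asc.geographic_distance_matrix(meta)

slope, intercept, r, p = asc.distance_decay(bc, geo, n_perm=999, seed=6)
print(f"distance decay: slope = {slope:.3e} per km (negative = decay), "
      f"r = {r:.3f}, Mantel p = {p:.4f}")

r_an, p_an = asc.anosim(bc, meta["site"], n_perm=999, seed=7)
print(f"ANOSIM (site): R = {r_an:.3f}, p = {p_an:.4f} "
      "(R near 1 = complete between-site separation)")

top = asc.simper(table, meta["site"], "site1", "site5").head(5)
print("\ntop SIMPER contributors to site1 vs site5 turnover:")
print(top.to_string(index=False))

ordination = asc.pcoa(bc)
res = asc.axis_vs_distance(ordination, meta["distance_to_land"], axis=1,
                           n_perm=999, seed=8)
print(f"\nPCoA axis 1 vs distance-to-land: Pearson r = {res['pearson_r']:.3f} "
      f"(p = {res['p']:.4f}); quadratic fit coefficients = "
      f"{tuple(round(c, 4) for c in res['quadratic'])}")
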