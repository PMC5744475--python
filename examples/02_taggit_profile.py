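"""TAGGIT seed-ontology profile of an up/down regulated gene list.

Profiles recovered DE sets over the 26 dormancy/germination categories
and contrasts them with a size-matched random control.  Category
percentages are of the direction totals; a random draw should show no
category structure.
"""

import dryseed as ds

cfg = ds.SimulationConfig(n_genes=2000, n_control_probes=20, rng_seed=2)
annotation, truth = ds.generate_annotation(cfg)
taggit_map, *_ = ds.generate_genesets(cfg, truth)

sets = truth.true_sets("ARvsD")
profile = ds.taggit_profile(sets, annotation, taggit_map)
top = profile.table.sort_values("down_pct", ascending=False).head(5)
print(f"profiled {profile.n_up} up / {profile.n_down} down genes")
print("top categories by down-regulated share (% of direction total):")
print(top[["up_pct", "down_pct"]].round(1).to_string())

genome = set(truth.table.index[~truth.table["is_control"]])
_, control = ds.random_control_profile(
    len(sets.up), len(sets.down), genome, taggit_map, annotation, seed=2, n_draws=50
)
print(f"random control over 50 draws: mean |up% - down%| = "
      f"{control['mean_abs_diff_pct'].mean():.2f} points (should be near 0)")
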