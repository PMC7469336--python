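"""Generate a synthetic study and measure seed clustering per structure.

The generator plants a region-level latent factor onto which the seed genes
load, with the loading graded by structure. The pipeline (mixed-model region
expression -> absolute-Pearson network -> leave-one-out seed CRs -> MRC)
should recover that gradient: higher MRC where the planted loading is
higher, ~0.5 where there is none.
"""

from seednet import (SimConfig, build_network, fit_region_expression,
                     generate, mrc, seed_cr_loo)

cfg = SimConfig(
    n_genes=300, n_seed=52, n_brains=6,
    regions_per_structure={"cerebrum_early": 30, "cerebrum_late": 25,
                           "cerebellum": 15, "brain_stem": 15},
    samples_per_region_per_brain=1,
    seed_module_loading={"cerebrum_early": 0.45, "cerebrum_late": 0.65,
                         "cerebellum": 0.0, "brain_stem": 0.35},
    rng_seed=1)
study = generate(cfg)
print(f"simulated {study.expression.shape[0]} genes x"
      f" {study.expression.shape[1]} samples "
      f"({cfg.n_brains} donors)")

region_expr = fit_region_expression(study.expression, study.annotations)
print("fitted donor-adjusted region expression:"
      f" {region_expr.values.shape[1]} regions\n")

print("structure group    planted loading   pipeline MRC")
for grp, regions in study.region_groups.items():
    net = build_network(region_expr, regions)
    m = mrc(seed_cr_loo(net, study.truth.seed_genes)["cr"])
    print(f"  {grp:16s} {study.truth.loadings.get(grp, 0.0):^15.2f} {m:.3f}")
print("\n-> MRC tracks the planted loading; with loading 0 the seeds rank"
      " like any other gene (MRC scatters around 0.5).")
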