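"""Rank a landscape's cells with the additive power-law benefit rule.

Builds the 52-layer baseline feature stack (Hmax, Hmean, Vol per species
plus DDW volume, each stratified by site class), ranks all cells by greedy
removal minimizing the loss of total benefit sum_j r_j**z with z = 0.25,
and reads the performance curves: the fraction of each feature's total
distribution captured by the top-ranked 2 % and 10 % of cells.

The concave benefit (z < 1) is what protects rarity: features wholly
concentrated in a few cells keep those cells ranked at the very top.
"""

import forestprio as fp

cfg = fp.ExperimentConfig(seed=42)
site, trees, ddw = fp.simulate_landscape(cfg)
stack = fp.build_baseline_stack(trees, ddw, site)
print(f"baseline stack: {len(stack)} layers at {stack.resolution:.0f} m, "
      f"{stack.n_cells} cells")

ranking = fp.rank_cells(stack, fp.BenefitConfig(z=0.25))
curves = fp.performance_curve(ranking, stack, fractions=[0.02, 0.10])

for p in (0.02, 0.10):
    row = curves.loc[p]
    aspen = row[[c for c in curves.columns if "aspen" in c]].mean()
    spruce = row[[c for c in curves.columns if "spruce" in c]].mean()
    print(f"\ntop {p:.0%} of cells protect on average:")
    print(f"  {aspen:.1%} of each aspen feature vs {spruce:.1%} of each spruce feature")
print("\nRare, concentrated features are captured at far higher fractions than "
      "their areal share — the signature of the additive benefit rule.")
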