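"""The full six-resolution experiment: how coarsening degrades priorities.

Aggregates the 16 m baseline stack to 32..96 m (mean for Hmean, max for
Hmax, sum for volumes), ranks each resolution independently, and scores
every coarse solution against the baseline: spatial overlap of the top
fractions, and per-feature conservation error evaluated on the baseline
data.  Negative conservation error means the coarse plan protects less of
that feature than the baseline plan would.
"""

import forestprio as fp

result = fp.run_experiment(fp.ExperimentConfig(seed=42))

print("spatial error (overlap with the 16 m baseline solution):")
print(
    result.spatial.pivot(index="resolution_m", columns="top_fraction", values="overlap")
    .round(3)
    .to_string()
)

cons = result.conservation
sel = cons[(cons.resolution_m == 96.0) & (cons.top_fraction == 0.02) & cons.defined]
print("\nmean conservation error at 96 m, top 2 % (by species):")
print(sel.groupby("species")["conservation_error"].mean().round(3).to_string())
print(
    "\nOverlap decays as cells coarsen, and the sporadic species (aspen) loses"
    "\nfar more of its attainable protection than the dominant conifers — the"
    "\nsparse-feature penalty of coarse input data."
)
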