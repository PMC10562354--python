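# Methods

This note documents the models behind `forestprio`, the defaults and why
they are what they are, the numerical choices, and what the synthetic
landscape can and cannot tell you about real data.

## Synthetic landscape

### Site-fertility grid

Classes are assigned by **quantile-thresholding a Gaussian-smoothed
white-noise field**: ranks of the smoothed field are cut at the cell quotas
implied by the configured shares (largest-remainder rounding), so every
achieved share is within one cell of its target by construction — the
property the acceptance target relies on. The smoothing length
(`smoothness`, default 80 m, i.e. 5 cells) sets patch size. Classes are
laid along the field's value axis in order f1…f4, which makes the rare
class f4 (0.9 %) appear as a few contiguous patches in the field's upper
tail rather than as scattered single cells — deliberately so: rare *but
clustered* strata survive aggregation far better than rare *scattered*
species, and keeping that contrast in the generator is what lets the
evaluation separate the two mechanisms.

### Tree point processes

Clustered species (spruce, pine, birch) follow a **Thomas process**:
Poisson parents (default 12 /ha, simulated on a 3-dispersion buffer so edge
clusters are not thinned), offspring displaced by an isotropic Gaussian
(default dispersion 15 m), with the realized pattern thinned cell-wise by
`intensity(site class)/max intensity` to modulate density by fertility.
Aspen is **homogeneous Poisson** ("sporadic") — single scattered stems.
DDW clustering statistics are unknown for the study system, so trunk
midpoints are uniform Poisson as well; this is a declared simplification,
not an inference.

Default per-class intensities (stems/ha):

| species | f1 | f2 | f3 | f4 | mode |
|---|---|---|---|---|---|
| spruce | 476 | 340 | 102 | 34 | clustered |
| pine | 200 | 340 | 550 | 500 | clustered |
| birch | 221 | 170 | 85 | 34 | clustered |
| aspen | 21.6 | 12 | 3.6 | 1.2 | sporadic |

These were chosen once, by matching truncated-normal moments of h³ against
the target landscape volume composition of roughly 40/35/17/5 %
(spruce/pine/birch/aspen) with spruce and birch favouring fertile classes
and pine poor ones; realized volume shares land near 44/38/14/4 % and stay
within the ±10-point calibration band, with aspen stems well under 10 % of
spruce stems. Heights are truncated normal on [2, 40] m with means 20/19/
18/28 m and s.d. 5/4/4/6 m — aspen few but large, as a sporadic
late-successional broadleaf should be.

### Allometry placeholders

The published Finnish DBH and stem-volume equations are not part of this
package; they are replaced by configurable monotone placeholders,
`dbh = a·h^b` (defaults a ≈ 1.0–1.15, b = 1) and the
cylinder-with-form-factor `v = c·dbh²·h·10⁻⁴` (c ≈ 0.42–0.47). Users with
access to published coefficients can substitute them per species via
`SpeciesParams`; every downstream computation only assumes positivity and
monotonicity.

### Downed deadwood

Segment midpoints Poisson (default 15 trunks/ha), orientation uniform,
length and diameter truncated normal (defaults 8 ± 4 m on [1, 30],
20 ± 8 cm on [5, 60]; ≈ 4 m³/ha). Volume is the cylinder
π/4·(d/100)²·L. Segments crossing the landscape boundary are clipped to it
and their length/volume recomputed from the clipped geometry — the edge
rule that keeps both record invariants (length = endpoint distance,
cylinder volume) and the rasterization conservation law exact.

## Feature grids

Cells are half-open `[x0, x0+cs)` with the far edge clamped inward, origin
top-left, row-major. Empty cells hold **0, not NoData**, inside the
landscape — required so block means and sums at coarse resolutions are
always defined; the alternative reading (ignore empty fine cells in Hmean
blocks) is exposed as `mean_mode="occupied"` but off by default. DDW volume
is allocated to cells in proportion to within-cell trunk length (exact
parametric splitting at grid-line crossings); a degenerate zero-length
record goes wholly to its containing cell. Stratification by site class is
a partition: per (variable, species) and cell at most one of the four
class layers is nonzero at baseline, and class layers sum back to the
unstratified layer for sum-type variables.

All coarse stacks derive **directly from the 16 m baseline** — never
chained through intermediate resolutions — so no rule-dependent path
ambiguity exists. The default resolution set {16, 32, 48, 64, 80, 96} m
requires extents divisible by 960 m (their LCM); non-tiling combinations
are rejected rather than given a partial-block edge rule.

## Prioritization

The additive-benefit removal rule with per-feature benefit `v_j(r) = r^z`,
z = 0.25 for every feature (species–area exponent), unit weights, no cost
layer (area-effective). Core-area (CAZ) removal, connectivity transforms
and hierarchical masks are out of scope. Zero-total features carry no
information and are dropped with a warning before ranking.

Numerical choices:

- **Tie-breaking** is deterministic lexicographic by (row, col); a seeded
  random permutation is available (`tie_rule="random"`). All-zero cells
  have loss exactly 0 and leave first under the tie rule.
- **Exhausted-feature snap.** `r_j − q_ij` and the running `r_j` are
  snapped to exact 0 below 1e-12. The running subtraction otherwise leaves
  ±1e-16 residues, and with z = 0.25 a residue of 1e-16 would contribute
  (1e-16)^0.25 ≈ 1e-4 of spurious benefit — the dominant error mode of the
  concave power near zero.
- **Engines.** The naive engine recomputes every marginal loss each
  iteration, O(N²F). The incremental engine caches the per-(cell, feature)
  loss terms and refreshes only columns whose `r_j` changed — necessary at
  10⁴+ cells. Both are exercised against each other and against a
  brute-force total-benefit oracle on enumerable stacks (≤ 12 cells,
  ≤ 4 features, 200 random trials, 1e-9).
- **Warp** (batch removal, default 1) removes the k smallest-loss cells per
  iteration, updating `r` once per batch; warp = 1 is the exact greedy.

Ranks: k-th removed of N gets k/N; the top fraction p is the ⌈pN⌉
highest-ranked cells, nested across p by construction.

## Evaluation

Overlap is normalized by the **baseline top-fraction area** (not the union
or the coarse footprint) — the only reading under which
overlap + omission = 1 with omission defined against the baseline. Coarse
top fractions use ⌈p·N_R⌉ coarse cells, so a coarse footprint may exceed
the baseline area by up to one coarse cell; footprint and baseline cell
counts are reported alongside. Conservation error for feature j is
`(S_j(coarse footprint) − S_j(baseline solution)) / S_j(baseline solution)`
with both sums taken over the **baseline 16 m data**; the reference is the
baseline solution's protected total, not each feature's theoretical
best-case selection (the alternative reading of "highest attainable
protection"; the methods-consistent choice is implemented). Features with a
zero baseline-protected total are flagged undefined rather than propagated
as NaN. Sum-type conservation errors are bounded below by −1.

## Reproducibility

All randomness flows from one config seed through `numpy.random.SeedSequence`
substreams (site grid / trees / DDW / tie-breaking), so a (config, seed)
pair reproduces every output byte-identically; each run writes its seed and
a hash of its scientific parameters into the reports. Rasters round-trip
bit-exactly through the ASCII-grid writer (17 significant digits).

## Problem sizes

The default experiment uses a 960 × 960 m landscape — 3600 baseline cells,
≈ 80 000 trees — for which the full six-resolution analysis takes a couple
of seconds per seed; the seed-averaged headline assertions use ten
replicates. Larger extents (multiples of 960 m) scale the ranking through
the incremental engine.

## What the synthetic landscape does not show

The generator reproduces the *statistical* structure the analysis needs —
composition, fertility stratification, clustered vs sporadic patterns, a
rare contiguous stratum, sparse linear DDW — not any real inventory.
Real-data effects that are deliberately absent: remote-sensing detection
bias (omission/commission of stems and trunks, which in the source system
made DDW spatially *more even* than reality), standing dead trees,
height-dependent detectability, spatial autocorrelation of allometric
errors, and landscape anisotropy (roads, stand boundaries). Passing tests
therefore demonstrate properties of the method under controlled structure —
e.g. that sporadic rare features lose disproportionally at coarse
resolution — not the magnitudes any particular real landscape would show.
Magnitude claims from the evaluation reports should be read as
seed-averaged tendencies of the simulated system.
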