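# Methods

This note records the models and procedures the package implements, the
defaults it ships, and the reasoning behind design choices that the
underlying experimental protocols leave open.

## Puncta detection and synapse calling

Each channel is Gaussian-smoothed (default σ = 0.05 μm, roughly half the
in-plane point-spread width), thresholded, and segmented into 6-connected
components. Components must pass dimension criteria — volume in
[0.02, 1.0] μm³ by default, bracketing typical immunofluorescent puncta at
high magnification — and an optional peak-SNR floor. Centers are
intensity-weighted centroids using above-threshold excess as weights (the
constant background therefore does not bias them), mapped to physical μm by
the center-of-voxel convention `(index + 0.5) × voxel size`; anisotropic
voxels are handled entirely by this physical mapping, and all distances are
Euclidean in μm.

Three threshold methods are available. `otsu` (default) is scale-equivariant
and adapts to puncta density, with a robust floor at median + 6·MAD-σ:
without the floor, Otsu's criterion splits the background mode whenever
puncta occupy a tiny volume fraction (a sparse complement channel), flooding
the detector with noise components. `quantile` reproduces a fixed
global-quantile threshold; `fixed` takes an absolute value. Because both
default methods are scale-equivariant, puncta counts are invariant to
uniform intensity rescaling of a channel.

A synapse is a presynaptic and postsynaptic punctum with center distance
**strictly** below 0.3 μm (a pair at exactly 0.3 μm does not count). Pairing
is one-to-one — a single punctum cannot support two synapses, which prevents
density-driven inflation — and is computed as a maximum-cardinality,
minimum-total-distance assignment (rectangular `linear_sum_assignment` with
a penalty cost for inadmissible pairs). A greedy nearest-first sweep is the
traditional implementation but is provably not maximum (pre A near posts 1
and 2, pre B near post 1 only: greedy pairs A–1 and strands B); the
assignment formulation is exact and is verified against a brute-force
augmenting-path oracle in the tests. An `any_neighbor` mode (every reference
with ≥ 1 probe in range counts) is available for comparison with
neighborhood-based analyses.

Co-localization of a probe channel (e.g. complement C3) with called synapses
is the percentage of synapses whose presynaptic center has a matched probe
punctum within the same distance threshold. An empty reference returns NaN —
an undefined ratio, not 0 %.

Two counting modes mirror the two acquisition styles: full-3D spot pairing
(structured-illumination-type stacks) and per-z-plane 2D counting
(confocal-type stacks, three fields × three planes per animal, the nine
plane values averaged to the per-animal number). Group effects are reported
as percent of the reference-group mean.

### Rotation null

Chance-level co-localization is estimated by rotating the probe channel 90°
in the imaging plane about the field center (non-square fields are
center-cropped). Rotation preserves intensity statistics, puncta density
and autocorrelation while destroying real spatial correspondence, so the
re-measured co-localization estimates the chance rate; subtracting it from
the observed value yields the above-chance tag fraction. For an independent
(untagged) probe the rotated and unrotated measurements agree to Monte
Carlo error, and the rotated level matches the closed-form chance rate
`1 − exp(−ρ·4πr³/3)` for a Poisson probe of density ρ — both are checked in
the test suite.

## Engulfment volumetrics

The cell is the thresholded connected component of the cell-marker channel
containing a user-provided seed point (an error if the seed is below
threshold). Then

* `percent engulfment = 100 × engulfed cargo volume / cell volume`,
* `input density = total cargo volume / field volume` (a dimensionless
  fraction in [0, 1]),
* `normalized engulfment = percent engulfment / input density`.

Normalization is volume-based; a count-based variant of "inputs in the
field" is deliberately not the default because volumes are what the
segmentation measures directly. Astrocyte scenes run the identical
procedure under a different cell-type label. Engulfed volume can never
exceed cell volume (hard assertion), and percent engulfment is invariant to
any intensity rescaling that preserves the thresholded voxel set.

## Phagocytic-state scoring

The 0–5 state is the sum of a 0–3 morphology score and a 0–2 CD68 score.
The underlying rubric is qualitative; reproducibility requires explicit
criteria, so the package scores from quantitative skeleton/CD68 features
through configurable bands (`ScoringBands`):

| score | rubric | operational band (defaults) |
|---|---|---|
| morphology 3 | no clear processes | no edges, or total length < 5 μm |
| morphology 2 | thick retracted processes, few branches | < 4 branch points |
| morphology 0 | thin long processes, multiple branches | ≥ 4 branch points, mean thickness < 0.7 μm |
| morphology 1 | thicker processes, similar branching | ≥ 4 branch points, thickness ≥ 0.7 μm |
| CD68 0 | no/scarce expression | volume fraction < 0.001 |
| CD68 2 | aggregated, or punctate all over | largest component ≥ 1 μm³, or fraction ≥ 0.02 |
| CD68 1 | punctate expression | everything between |

These cutoffs are declared assumptions, chosen so that archetypal cells of
each class (as produced by the generator) score correctly; they are not
measured constants and every one is configurable. Populations outside the
recommended 30–50 cells per animal trigger a warning, not an error.

Sholl profiles count, per concentric shell (default 5 μm step), the exact
number of skeleton-segment crossings of each sphere (quadratic
segment–sphere intersection; a segment entering and leaving counts twice,
tangential grazes count zero), plus branch points and terminals per shell.

## sEPSC bootstrap

Event tables (times, amplitudes, recording duration per cell) are consumed
as-is; raw-trace event detection is upstream and out of scope. To weight
every cell equally regardless of its recorded event count, each bootstrap
iteration draws 100 events per cell with replacement and pools them, so an
iteration always holds n_cells × 100 values.

* **CDF band** — 1,000 iterations; the pointwise variance of the pooled
  empirical CDF across iterations is the error band.
* **75th-percentile test** — 5,000 iterations; per iteration both groups'
  pooled 75th percentiles (linear interpolation) are compared. With
  f = fraction of iterations in which A's quantile exceeds B's (ties count
  0.5 to each side), the two-sided p is `2·min(f, 1 − f)`, floored at
  1/n_iterations — 0.0002 at 5,000, the procedure's detection threshold.
  One-sided alternatives are available by flag; two-sided is the default.
  Each group's resampling stream is keyed by (seed, group content), making
  the p-value exactly invariant under swapping the groups.

Calibration: the bootstrap spread of a group quantile approximates its
sampling variability when the per-cell draw (100) is comparable to the
recorded events per cell. When cells record many more events than are
drawn, the test becomes conservative — the bootstrap overstates the
sampling variance roughly by the ratio of recorded to drawn events — which
is the safe direction for a screening comparison. The type-I calibration
test therefore runs in the matched regime (~100 recorded events per cell),
where the measured null rejection rate at p ≤ 0.05 is near nominal.

## Cohort staging and analyte statistics

* `CAP = 100 × age × (CAG − 30)/627` — L = 30 anchors the lower end of
  pathologically relevant repeat lengths; S = 627 normalizes the score to
  ≈ 100 at the expected onset age. CAP below 30 repeats is returned with a
  warning rather than an error.
* `burden = (CAG − 35.5) × age`; premanifest carriers split at 250.
* Stratification: early premanifest (dcl < 4, CAG ≥ 40, burden < 250), late
  premanifest (dcl < 4, CAG ≥ 40, burden ≥ 250), early manifest (dcl = 4,
  CAG ≥ 36, TFC 7–13 inclusive), healthy (CAG ≤ 35, no motor diagnosis),
  otherwise unclassified (e.g. intermediate alleles 36–39 without motor
  diagnosis). The literature wording leaves burden exactly 250 unassigned
  ("< 250" vs "> 250"); it is assigned to late premanifest here so the two
  groups partition the premanifest carriers without a gap. "UHDRS score" in
  the criteria is interpreted as the diagnostic confidence level (0–4),
  consistent with the "< 4" / "= 4" usage; the field is named `dcl`.
* Age adjustment: `adjusted(y) = y − b·(age − mean control age)` with b the
  OLS slope of the analyte on age in ≥ 3 controls. Adjusting the controls
  themselves and re-fitting returns slope 0 to numerical precision.
* Group comparisons: Kruskal–Wallis (scipy) with Dunn's pairwise z-tests —
  implemented in-package with the standard tie-corrected formula and
  Bonferroni family-wise adjustment at α = 0.05, validated against a
  hand-computed example. Disease-burden association: two-tailed Spearman of
  CAP vs analyte (constant analytes return an explicit `undefined` flag).
  Sex is carried in the tables but not entered as a covariate by default.

## Synthetic data: what it emulates and what it does not

The generators define the study conditions for all parameter-recovery
tests. One root seed; each generator derives an independent stream keyed by
stage name, so outputs are bit-reproducible and stages cannot perturb each
other.

**Puncta fields.** Homogeneous Poisson presynaptic puncta (default
0.3/μm³ in a 12.8 × 12.8 × 3 μm field with 0.1 × 0.1 × 0.3 μm voxels —
plausible for dense neuropil at high magnification; the source protocols do
not state densities or SNR, so these are free parameters of the config). A
binomial `coloc_fraction` (default 0.6) of pre puncta gets a post partner
uniformly within a 0.15 μm ball — safely inside the 0.3 μm call threshold so
every true pair is callable. Complement tags a binomial fraction (default
0.4) of true pairs, over a 0.05/μm³ independent background (the background
is what gives the rotation null something to measure). Spots render as
isotropic-in-plane Gaussians (σ = 0.08, 0.08, 0.2 μm) at peak SNR 10 over a
constant background of 10 counts with Poisson shot noise. The disease-like
scenario is the reference recipe with pre-density scaled by 0.5 — the
magnitude of loss the pipeline exists to detect. Not emulated:
autofluorescence, vasculature, tissue-depth attenuation, optical
aberrations, or clustered (non-Poisson) synapse arrangements — so passing
recovery tests demonstrates correctness of the measurement chain, not
robustness to every tissue artifact.

**Engulfment scenes.** A volume-preserving random ellipsoid
(default 1,000 μm³) holds `round(fraction × n_cell_voxels)` cargo voxels;
extracellular cargo fills `cargo_field_density` of the field. Channels are
binary-valued and noise-free by default, because the recovery guarantee
(±1 voxel volume) is about the volumetric arithmetic, not detection
robustness; additive noise is available by parameter. An unreachable
requested fraction raises an error stating the achievable quantum
(1/n_cell_voxels).

**Morphologies.** Archetypes per class: five primary processes with two
bifurcation levels (thin 0.4 μm for class 0, thick 1.0 μm for class 1), two
short thick unbranched processes (class 2), no processes (class 3); CD68
absent / five small puncta / one ≥ 2 μm³ aggregate for classes 0/1/2. The
intent 0–5 decomposes as morphology `min(intent, 3)` + CD68 remainder.

**Event trains.** Exponential ISIs (default 2 Hz), log-normal amplitudes
(μ = 2.7, σ = 0.4 → median ≈ 15 pA), Poisson event counts (default mean 600
≈ 5 min at 2 Hz); a second group scales rate and amplitude multiplicatively.
No cell-level random effects are simulated, so between-cell variance is
purely sampling noise — relevant when interpreting the bootstrap's
between-cell behavior on real data, where slow cell-to-cell heterogeneity
would widen true bands.

**Cohorts.** Group sizes default to the CSF study layout (20 controls, 13
early premanifest, 18 late premanifest, 32 early manifest). CAG and age are
sampled inside per-group ranges and re-sampled until the burden criterion
holds; every generated subject re-stratifies into its intended group by
construction (asserted at generation). Analyte =
`300 + 2·age + 1.5·CAP (carriers) + N(0, 20)` in assay units — slopes and
noise chosen to give a clearly positive but noisy CAP correlation, the
regime the statistics are designed for.

## Problem sizes

The bundled test-suite sizes are the package's own verification choices:
1,000 random instances for the matching oracle; 6 animals × 3 fields per
group for imaging recovery; 50 scenes for engulfment recovery; 500 null
replicates at 500 bootstrap iterations for type-I calibration; 200
replicate fields for generator statistics; smaller per-example fixtures
elsewhere. The full suite runs in well under a minute per module on a
single CPU.

## Numerical notes and edge cases

* Pair distances are compared strictly (`<`); ties at the threshold are
  excluded everywhere, matching the strict wording of the call criterion.
* The assignment penalty cost is `max_distance × (n_a + n_b + 1)`, large
  enough that one extra real pair always beats any total-distance saving.
* Quantiles use linear interpolation (`numpy.quantile` default).
* Empty references (co-localization), empty populations (scoring), groups
  with a cell lacking metric values (bootstrap), < 3 controls (age model)
  and degenerate group layouts (Kruskal–Wallis) raise or flag explicitly
  rather than returning silent zeros.
* Detection on an empty or constant channel warns and returns an empty spot
  set.

## Known limitations

* The morphology/CD68 bands operationalize a subjective rubric; agreement
  with any particular rater is not claimed, only internal consistency.
* Presynaptic boutons cannot be distinguished from axonal fragments or
  exosomes in engulfment scenes — the measurement counts labeled cargo.
* Image registration, deconvolution, array-tomography alignment and
  trainable segmentation are out of scope; inputs are assumed aligned.
* Onset-prediction formulas from survival modeling are not included; the
  burden score split is the only premanifest sub-staging provided.
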