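# Methods

## Scope and model

`imrtqa` quantifies two things for step-and-shoot IMRT plans delivered on
a dual-stacked-MLC 0.35 T MR-linac:

1. **Plan complexity** — 23 metrics computed per plan from the delivery
   record (gantry angle, segment MU, leaf positions of both MLC stacks),
   including the two tissue-heterogeneity indices THI and DWTHI that
   need a CT volume and a dose distribution in addition to the plan.
2. **Deliverability QA** — a 3D gamma comparison between a planned dose
   distribution and an independently recomputed one, with the gamma pass
   rate (GPR) as the summary statistic, plus Pearson correlation of
   complexity metrics against GPRs over a cohort.

Monte Carlo dose recomputation itself is out of scope: the package
consumes dose grids, it does not produce them.

## Machine geometry and aperture rasterization

The machine model is intentionally minimal: two stacked MLC banks
(34 and 35 opposed leaf pairs; 68 + 70 leaves), leaf width 0.83 cm
projected to the 90 cm source-axis distance, bottom stack shifted inline
by half a leaf width. Leaf ends, tongue-and-groove, transmission and
physical leaf height are not modelled — apertures are ideal binary
projections.

Each stack is rasterized onto a shared beam's-eye-view grid of
0.01 cm (crossline) × 0.415 cm (inline) pixels; the composite aperture
is the logical AND of the two stack images. The half-leaf stagger means
every 0.415 cm composite row is covered by one top leaf and one bottom
leaf (except the two outermost rows, covered by the bottom stack only),
so the composite row is the natural "effective leaf pair" of this
machine.

Numerical choices:

* **Containment rule.** A pixel is open iff its crossline center lies in
  the half-open interval `[left, right)` of the covering leaf pair, with
  a 1e-9 cm boundary tolerance. This makes a closed pair
  (`left == right`) rasterize to nothing, makes pixel counts exact for
  edge-aligned intervals (a 2.00 cm opening is exactly 200 columns), and
  resolves grid-boundary ties deterministically.
* **Extents.** Columns span a fixed ±14.0 cm (2800 columns), larger than
  any physical field; rows span the bottom stack (70 rows). All metrics
  are extent-invariant provided apertures fit, which validation
  guarantees.
* **Edge classification.** Exposed pixel edges at constant crossline
  coordinate are leaf-tip faces (0.415 cm each); edges at constant
  inline coordinate are leaf sides (0.01 cm each). Total perimeter is
  their sum; the edge metric uses only the side component.
* **Connectivity.** Openings are 4-connected components; diagonal
  contact counts as separate openings.

## Complexity metrics

Per-plan aggregation weights each segment by its MU fraction
`w_s = MU_s / ΣMU`; pure counts (number of segments, active pairs,
unique opening index, MU totals) are plain sums. "Leaf positions" for
the position-based metrics (LSV, SAS, MAD, cross-axis, leaf travel) are
the **outermost** open-pixel edges per composite row; rows with multiple
open runs expose the per-run intervals through `RowProfile` but metrics
use the outermost edges, since the composite image is the only
well-defined per-row aperture on a dual-stacked machine.

Definitions that were genuinely open and how they were fixed:

* **AAV** normalizes each segment's summed row gaps by the per-row
  maximum gap across all segments of the same plan (union rows), so
  AAV ≤ 1 with equality when every segment realises its per-row maxima.
* **MAD** measures row midpoints against the segment's mean midpoint
  (not against x = 0), making it translation-invariant; crossline
  translation then changes only the cross-axis score.
* **LTI** averages per-(row, side) leaf travel over consecutive segments
  in which the row is active in both, normalized to 100 cm; rows parked
  in either segment contribute no transition, because travel of a parked
  effective pair is undefined in the composite representation.
  LTIMCS = (1 − LTI/10)·MCS.
* **MUs per segment** is the plain mean MU per segment (total MU / number
  of segments).
* **LSV** per bank is the McNiven form over consecutive active rows,
  defined as 1 when all positions coincide or a single row is active;
  plan LSV/AAV/MCS are the MU-weighted per-segment values, with
  MCS_s = LSV_s·AAV_s weighted as a product.

## Tissue heterogeneity indices

THI sums the HU spatial-gradient magnitude over all CT voxels receiving
strictly more than 10% of the maximum dose; DWTHI additionally weights
each voxel by its relative dose. Gradients are central differences over
the physical spacing, one-sided at volume borders — exact on linear HU
fields, which gives the analytic ramp-phantom tests their closed-form
expectations. When dose and CT grids differ, the dose is trilinearly
resampled onto the CT grid (the gradient lives there); CT voxels outside
the dose extent count as zero dose. The threshold dose defaults to the
supplied (planned) distribution and the threshold fraction is
configurable. Both indices are reported in HU/mm; D_rel is unitless, so
dose weighting does not change the unit.

## Gamma analysis

The QA chain: optional 3×3×3 median filter on the recomputed (noisy)
distribution — border voxels use the truncated neighborhood — then
trilinear resampling of the planned distribution onto the recomputed
grid, then global gamma with the planned distribution as reference. By
default both inputs are normalized to their own maxima first (relative
comparison); absolute mode is available.

Gamma parameters default to 3%/3 mm with a 10% low-dose threshold
defined on the reference. The minimization samples displacements on a
dense grid of pitch 0.1·DTA within a sphere of radius 3·DTA,
interpolating the evaluated dose trilinearly. The production search
visits displacements sorted by radius and stops when the spatial term
alone exceeds the current best gamma — an exact pruning, so the fast
path and the exhaustive brute-force scan (kept as an independent
implementation for verification) agree to floating-point precision; the
test suite asserts GPR agreement within 0.1% and per-voxel gamma within
0.01 on seeded random pairs, and observes ~1e-14 in practice. Reference
voxels outside the evaluated grid's extent are excluded from the
evaluated mask. Both kernels are numba-compiled; the first call in a
process pays a few seconds of JIT compilation.

Loosening either tolerance never decreases GPR in practice; this is
asserted on fixtures. It is not a strict theorem under displacement
re-gridding (the candidate pitch scales with DTA), but margins on smooth
fields dwarf the re-gridding perturbation.

## Correlation statistics

Pearson r with the two-sided p-value from the t transform on n−2
degrees of freedom (via `scipy.stats.pearsonr`). Significance defaults
to p ≤ 0.01: with the cohort-style printed precision this reproduces a
"7 of 23 significant" style of count, whereas 0.05 would admit weaker
rows. No multiple-testing correction by default; Benjamini–Hochberg is
available. Metrics that are constant or non-finite across the cohort
(THI/DWTHI without a CT) are dropped with a warning. Nonlinear
association measures are out of scope.

## Synthetic fixtures

The generator is first-class, seeded, and a pure function of its spec:

* **Plans** default to 77 segments (cohort-scale mean) with lognormal
  MU of arithmetic mean 46.5 MU per segment, putting total plan MU near
  3.6k — the scale of clinical SBRT cohorts on this machine. Aperture
  styles: `rectangle` (identical per-row intervals), `random-contiguous`
  (per-row intervals following a bounded random walk), `multi-hole`
  (alternating row bands over two disjoint crossline regions). Styles
  are built row-wise and projected to per-pair intervals, so every
  physical leaf pair stays contiguous.
* **Phantoms** are 20×20×20 grids at the planning voxel size
  (2 × 3 × 2 mm, 3 mm along the magnetic-field axis): uniform HU,
  water/−700 HU lung/water slab, or a linear HU ramp with known slope.
* **Dose pairs** are uniform or Gaussian-blob references; the evaluated
  copy adds sharp-edged cubic perturbations specified as fractions of
  the maximum reference dose (so global-gamma failure depth is analytic)
  and optional i.i.d. Gaussian noise. The expected gamma fail mask is
  computed by the exhaustive oracle at generation time and stored with
  the pair.

What the fixtures do **not** emulate: real anatomy, realistic fluence
patterns produced by an optimizer, correlated Monte Carlo noise, and
machine delivery errors. Passing tests therefore demonstrate
correctness of the computations and their invariances, not clinical
performance on patient data.

## Problem sizes and tolerances

Default test/acceptance problem sizes: 20³ dose grids, 25 random pairs
for the oracle-equivalence check (Gaussian-blob σ ≈ 8 mm keeps the
evaluated mask at 1–3k voxels), 20 five-segment plans for brute-force
metric equivalence (agreement required at 1e-9 relative), 500 null
replicates for p-value uniformity, n = 1000 for correlation recovery
within the Fisher-z 99% interval. A cohort-scale 77-segment report with
CT and dose completes in well under a second on one CPU.

## Known limitations

* DICOM readers assume identity-oriented axial series; oblique
  orientations are rejected territory (not detected — supply the
  internal grid format instead). DICOM RT Plan is not parsed; plans
  travel in the package's JSON/CSV dialect.
* The composite-image representation cannot distinguish which stack
  limits a row's opening; metrics defined on "physical leaves" are
  therefore effective-pair metrics here.
* Gamma is deterministic on its inputs; statistical-uncertainty-aware
  gamma variants are not implemented.
* AAV and MUs-per-segment have competing definitions in the literature;
  the ones used here are documented above and capped/normalized as
  stated, and may differ from other implementations.
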