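# Methods

## Scope and model

`palmcount` quantifies single-molecule PALM counting data from paired
pre-activation / activation videos.  The analysis model assumes an
irreversibly photoactivatable fluorophore (PAmCherry1-like): activation
happens at most once per molecule, is followed by permanent bleaching, and
reversible blinking is negligible.  Overcounting therefore comes only from a
fluorophore emitting longer than one camera exposure, which the 30 nm /
10-frame merge removes; undercounting comes from molecules that never
photoactivate or are lost to background, which the depth-calibration step
absorbs into a per-plane detection factor.

## Merge semantics

Localizations are linked iff their Euclidean distance is ≤ 30 nm and their
frame gap is between 1 and 10; same-frame pairs never link directly (two
simultaneously active emitters are two molecules).  A molecule is a
connected component (single-linkage) of this relation, its position the mean
of its appearances.  Single-linkage was chosen over greedy frame-order
linking because it is order-independent, has an exact brute-force
specification the implementation is tested against, and the two differ only
in the rare configuration where two same-frame localizations both fall
within the radius of one earlier appearance.  The frame window is
configurable; chaining across gaps (dark frames) up to the window is
allowed.

With a per-frame localization precision σ ≈ 23–31 nm, the displacement
between two appearances of one molecule is Rayleigh with scale σ√2 ≈ 33 nm,
so an appreciable fraction of consecutive appearances falls outside the
30 nm radius and a single fluorophore can split into >1 merged molecule
(≈1.6× at σ = 23 nm, mean on-time 3 frames).  This inflates absolute counts
but is identical between samples at the same depth and cancels in all
calibrated and normalized quantities; it is reported here so absolute
densities are read with care.

## Segmentation and its regime of validity

The analysis area is built directly from the localization map: a 1 µm
diameter disk around every merged molecule, summed per pixel (default
reconstruction pixel 20 nm — the raster value counts emitters within a
fixed physical radius, so thresholds are pixel-size independent).  Pixels
with value in (0, 150] are cell area; pixels above 150 are "torches"
(cells with strong activation-independent emission) and are excluded.  The
lower threshold "0" is read as strictly greater than zero and the upper
"150" as inclusive, the only reading that makes both thresholds active.
Torch exclusion is pixel-wise by default; a whole-component mode (any
8-connected component containing a torch pixel is removed entirely) is
available for sparse scenes where a torch's dim rim should not survive.
The map is built from merged molecules by default (raw localizations
selectable), which keeps typical cell values comfortably inside (0, 150].

The density ρ = count / segmented-area is linear in the true molecule
density only inside a bounded window.  Below it, disks around isolated
emitters stop overlapping and the area scales with the count, so ρ floors
at ≈ 1 / (π·0.5²) ≈ 1.27 µm⁻²; above it, the 150 threshold truncates the
densest pixels (e.g. where cell footprints stack), clipping count faster
than area.  Empirically the window spans roughly a 12–17× range of local
merged-molecule density.  Within it the measure is accurate; outside it the
bias is one-sided (sparse planes read high relative to dense planes after
normalization).  The synthetic study conditions below are placed inside
this window, and users comparing conditions spanning much more than an
order of magnitude in density should expect compression at the sparse end.

## Base-level correction

The spurious (photoactivation-independent) localization rate is modelled as
N(f) = A·e^(−b·f), fitted by least squares on the per-frame counts of the
mask-restricted pre-activation video (Levenberg–Marquardt via
`scipy.optimize.curve_fit`, initialized from a log-linear regression on
binned positive counts; non-convergent fits fall back to the log-linear
estimate and are flagged).  An optional constant floor c is off by default:
the two-parameter decay is the simplest form consistent with a
bleaching autofluorescent background, and a floor is unidentifiable on
near-constant series (flagged as degenerate when fitted).  The predicted
spurious count is the continuous integral over frames 1001–2000,
(A/b)(e^(−1001·b) − e^(−2000·b)), computed analytically; a discrete frame
sum differs by O(b) relative (&lt;1% at b = 0.005) and is selectable.
Corrected counts are clamped at zero and flagged, since a density cannot be
negative.

## Densities, calibration, aggregation

Per-FOV density is corrected count / segmented area with Poisson error
√count / area.  The calibration profile divides each plane's weighted-mean
density in the uniform sample by the coverslip value; biofilm densities are
divided by the factor of their plane.  The factor's uncertainty is a
*systematic* shared by every FOV of a plane, so calibration scales each
FOV's statistical error by 1/factor and carries the factor's relative error
separately, folding it into the aggregated mean error in quadrature.
Putting it into the per-FOV weights instead would distort inverse-variance
weighting and average down an error that does not average down; it would
also break the exact identity that calibrating a sample by its own profile
yields unit factors, which the test suite asserts to 1e-9.  Depth profiles
use inverse-variance weights by default (error of the weighted mean
√(1/Σw)); segmented-area and equal weights are available.  Group
comparisons default to the equal-variance two-sample Student's t-test
(Welch optional), with FOVs pooled as the unit of analysis.

## Synthetic acquisitions

The generator emulates the acquisition geometry: spherocylindrical cells
(2 × 1 µm) in a 10 × 40 µm² FOV at planes 0/4.5/9/13.5 µm, lying flat at
the coverslip and isotropically oriented deeper (horizontal fraction
max(0, 1 − z/10); isotropic tilt has sin ψ uniform, shortening the
projected footprint), overlap allowed as in dense biofilms.  Molecule
counts per cell are Poisson(density × projected footprint area), positions
uniform in the footprint.  Emitters activate at most once (per-frame
probability 0.005, keeping ~0–2 fluorophores active per cell at any
moment), emit for a geometric number of frames (mean 3), and are detected
with probability e^(−z/20 µm) at depth z with isotropic Gaussian
localization noise σ(z) = 23 + 0.08·z nm.  Spurious localizations follow
10·e^(−0.005·f) per frame — the canonical decaying background used
throughout the validation suite — continuing across the video boundary and
placed uniformly within cell footprints (an optional free-background
fraction exists).  Five percent of cells are torches emitting 2
activation-independent localizations per frame.  Quality fields are uniform
inside the filter-passing ranges except a 5% outlier fraction violating one
randomly chosen filter condition.  Every emitter carries a hidden identity
written to a sidecar file, never into the CSV.

Study-condition defaults: 180 cells per plane (a near-confluent base layer,
as in a real biofilm) and 40 molecules/µm² of footprint (~70 molecules per
cell, a plausible endogenous efflux-pump level).  These place all planes of
both the uniform calibration sample and the (1, 0.6, 0.3, 0.1) biofilm
gradient inside the density measure's linear window described above; with
them the calibrated normalized profile is recovered to ≤ 0.06 absolute per
depth (tolerance 0.10) across independent seeds, and halving all densities
is detected at p < 1e-9 per depth.

What the generator does *not* emulate: raw camera frames and PSF fitting
(tables are generated directly), 3D axial localization within a plane,
drift, dark-state blinking, spatially structured autofluorescence, and
cell-shape variability.  Passing tests therefore validate the counting,
segmentation, correction and calibration logic — not the upstream
reconstruction, nor robustness to photophysics beyond the single-activation
model.

## Numerical and design choices

- Reconstruction pixel size 20 nm (not stated in the printed parameters;
  thresholds are invariant to it by construction).  Positions are
  continuous nm; pixel membership uses the floor convention, points on a
  boundary belong to the higher-index pixel.
- Disks are truncated at the FOV boundary; no wraparound.
- Acquisition ordering: lateral positions from the grid center outward
  (squared distance, ties by angle), the full depth stack at each position
  before moving on — one concrete realization of "never pre-illuminate a
  pending FOV"; the exact order used on the instrument is not prescribed.
- Sheet thickness is an informational config input; only the inclination
  equation θᵣ = sin⁻¹(d/(n·f)) is computed, with a domain error at
  |d| ≥ n·f.
- All randomness flows from a single seed through a spawned seed tree
  (replicate → lateral position → scene/depth), so studies are reproducible
  FOV by FOV and outputs are byte-identical across reruns.
- Degenerate inputs: empty tables, all-zero count series, zero segmented
  area and missing calibration depths are flagged or raised explicitly
  rather than propagated as NaN.

## Problem sizes

The validation suite and the acceptance script run the full printed
acquisition scheme (3 × 3 × 4, 36 FOVs per condition) with one replicate
per condition; the replicate machinery (three biological replicates pooled
at the FOV level) is implemented and exercised at smaller grid sizes.

## Known limitations

Absolute molecule counts are inflated by merge splitting (see above) and
deflated by incomplete photoactivation; only depth- and condition-relative
quantities are calibrated.  The base-level subtraction predicts spurious
*localizations* but is subtracted from *merged* counts, a small intrinsic
mismatch of the procedure (&lt;1% under the default conditions).  The
t-test treats FOVs as independent, which understates uncertainty if FOVs
within a replicate are correlated.
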