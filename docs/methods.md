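# Methods

This note documents the models, estimators and numerical choices behind
`srcamap`, in the spirit of a methods appendix: what is assumed, what is
tunable, and what the synthetic tests do and do not demonstrate.

## The measurement model

A scanning-XRF acquisition yields per-pixel photon counts for Ca and Sr.
Ca is a major, nearly homogeneous matrix element of aragonite, so the Ca
map doubles as the otolith silhouette; Sr varies with the salinity of the
ambient water at deposition time. The quantity of interest is the molar
ratio

  Sr:Ca [mmol·mol⁻¹] = k · (I_Sr / I_Ca),

with the calibration coefficient *k* coming from an external spectral
quantification of the same acquisition. The package deliberately does not
re-implement fundamental-parameter XRF quantification: *k* is a single
user-supplied multiplier (config `calibration.k`, default 1 with provenance
`"identity (uncalibrated)"`). All decision thresholds are stated on the
molar scale, so uncalibrated runs are only meaningful if the intensity
ratio is already on that scale — the provenance string in every report
makes this loud.

Division artifacts are handled by masking: a pixel with `I_Ca = 0` leaves
the valid set. Nothing downstream (histograms, transects, patches) ever
sees an invalid pixel.

## Otolith masking

Ca intensity is strongly bimodal (empty background vs. otolith). The
default mask operator is an Otsu split followed by largest-connected-
component selection and hole filling; a quantile threshold is available
when the distribution is known. A degenerate (constant) image yields a
full-frame mask with a warning rather than an error, so pathological
inputs surface visibly but do not crash batch runs.

## Core, transects and change-point zonation

- **Core.** Default: centroid of the otolith mask. Refinement: the
  elevated-Sr:Ca band (Otsu split of valid ratio values, Gaussian
  pre-smoothing σ = 1.5 px) is concentric around the true core, so its
  centroid tracks the core even when the outline is skewed; the refinement
  is only accepted when the high band is a meaningful fraction of the
  otolith (2–85 %) with real level contrast (> 1.3×), otherwise the mask
  centroid stands. A manual `(x, z)` override always wins.
- **Transects.** Nearest-pixel samples at pixel-size steps along the full
  chord through the core; the chord ends at the first departure from the
  (hole-filled) otolith mask on each side. Samples on invalid pixels are
  carried as NaN. Smoothing is a NaN-aware moving mean over a window of
  2.5 µm (5 px at the default 0.5 µm pixel) — the smallest window that
  suppresses single-pixel counting noise without displacing step edges
  (a symmetric window does not bias a step's midpoint).
- **Boundaries.** Each side of the transect is fitted with exactly
  `n_zones` constant segments by exact dynamic programming on the within-
  segment sum of squares (minimum segment length 3 samples). A constant
  transect has no admissible segmentation and raises, pointing to the
  manual-threshold path. The DP is O(n²K) on ≤ ~600-sample transects —
  microseconds in practice.
- **Consensus segmentation (`radial`).** Transects at `n_angles = 16`
  angles contribute two sides each; every detected boundary is expressed
  as a fraction of that side's otolith radius, and the per-boundary median
  over all sides defines the concentric partition. Zone bands therefore
  scale with the local otolith radius — an assumption, not a measurement;
  for strongly non-similar real zone shapes the manual-override path
  (explicit thresholds or a supplied label TIFF via `ZoneLabelMap`) is the
  honest route. Per-pixel fractional radius uses a ray-marched
  edge-distance table (1440 directions, 0.25 px steps, periodic linear
  interpolation), valid for star-convex outlines.
- **Value-threshold segmentation (`threshold`).** Multi-Otsu (or user)
  thresholds classify pixels by value; the concentric partition is then
  recovered as an exact weighted 3-segment least-squares fit of the class
  index over 512 annular bins of fractional radius. Two bands may share a
  value class — Z1 and Z3 are both low-Sr in the classic pattern — which
  is precisely why the projection is positional rather than a bijection
  from class to zone.

Zone labels are validated to partition the mask after every segmentation;
Z1 is a single connected component containing the core by construction of
the concentric partition.

### Accuracy limits

On noise-free synthetic scans the radial method reproduces the true labels
on ≈ 99.6 % of otolith pixels. The residual is confined to one-pixel bands
at the three digitized boundaries: a segmentation that does not know the
zones are perfect ellipses cannot beat the disagreement between the
digitized mask boundary, the ray-marched radius estimate and the analytic
elliptical metric. Boundary radii themselves are recovered to well under
1 µm (noise-free) and ~1–3 µm under the default counting noise.

## Per-zone statistics

Histograms use bin edges at multiples of `bin_width` (default
0.25 mmol·mol⁻¹) shared across zones, so per-zone histograms mix exactly
into the whole-otolith histogram. Frequencies are normalized per zone
(count / valid pixels of the zone); the reporting view zeroes bins under
`frequency_threshold` (default 1 %) while the raw histogram is retained.
The mode is the centre of the maximal bin (ties → lower bin); mean and max
come from raw pixel values. Note the max of a noisy ratio map is an
extreme-value statistic dominated by low-Ca-count pixels; it is reported
as evidence but only the estuarine-hatch flag consumes it.

Marine patches are 8-connected components of valid Z2 pixels above
`marine_threshold` (default 6 mmol·mol⁻¹). Components under
`min_patch_area_um2` (default 10 µm², i.e. 40 px at 0.5 µm — single-pixel
speckle) are dropped from the patch list, but the marine area fraction of
Z2 is computed before that filter. With a hard threshold on noisy data,
patch areas are eroded in proportion to the noise level at the patch
Sr:Ca; patch *counts* are robust, areas are only accurate when the patch
level sits several noise standard deviations above the threshold.

The granularity index is the median over zone pixels of the local
coefficient of variation (stdev/mean in a square window, default 5 µm,
minimum 3 px), mask-aware and invariant to global rescaling.

## Classification

Thresholds (`ClassifierConfig`): `fw_upper = 4`, `marine_lower = 6`,
`estuarine_z1 = 5` mmol·mol⁻¹ — the standard freshwater/marine proxy
ranges — and `patch_fraction_min = 0.05`, which has no published value:
it demands a small but unmistakable marine footprint (5 % of Z2 area)
before calling marine passage, and is exposed in config with that caveat.
Rules in order: classic (Z2 mode marine, Z3 mode freshwater), patchy
(freshwater Z2 mode, patch fraction ≥ minimum, freshwater Z3), resident
(freshwater Z2 and Z3 modes, patch fraction below minimum), else
indeterminate — an abstain state is deliberate. Z1 never enters the main
category: hatching under estuarine influence is real and compatible with
lifelong freshwater residency, so an elevated Z1 maximum only sets the
`estuarine_hatch` flag (and is skipped when the call is classic, where a
marine-influenced Z1 carries no extra information). The call is a pure
function of evidence + config; raising `marine_lower` can only move calls
away from classic.

## The synthetic generator

The generator emulates exactly the structure the analysis assumes:

- elliptical otolith (default semi-axes 140 × 90 µm in a 600 × 400 px
  frame at 0.5 µm/px, matching the sub-400 µm scale of real sagittae) on
  an empty (zero-count) background;
- smooth Ca dome (10 % centre-to-edge falloff) at `ca_intensity` counts —
  the default 10⁴ is arbitrary, since absolute per-pixel count statistics
  for such acquisitions are not published;
- concentric zone ellipses sharing the otolith aspect ratio, centred on
  the core, with outer semi-major extents 15 and 90 µm by default (Z1
  equivalent diameter ≈ 24.5 µm, inside the 20–30 µm range reported for
  real cores);
- Sr = Ca × zone level (identity calibration), optionally modulated by
  hard marine discs placed fully inside Z2 with a minimum edge separation
  (so ground-truth patch counts are well-defined), multiplicative
  Gaussian-field granularity, and a radial sinusoid at the Z2/Z3 boundary
  (rings);
- per-pixel scaled-Poisson counting noise: counts = Poisson(mean/d²)·d²,
  variance d²·mean. d = 1 is pure photon counting; the default d = 20
  absorbs detector and spectral-fitting noise and yields per-zone Sr:Ca
  spreads (≈ 0.5 mmol·mol⁻¹ at freshwater levels, ≈ 1.5 at marine levels)
  comparable to real per-zone frequency curves. `kind="none"` gives exact
  maps for construction tests.

Presets map life-history phenotypes to level ranges: classic (Z1 3–5,
Z2 6.5–9, Z3 1–2), patchy (visible low Z1, freshwater Z2 base, 5–8 discs
of radius 8–12 µm at 7–12 mmol·mol⁻¹), resident (all < 4 with preserved
Z1 > Z2 > Z3 contrast), estuarine hatch (6 / 3 / 0.8), and an extreme
variant with patches up to 16 mmol·mol⁻¹. Fixed seeds give bit-identical
rasters.

What the generator does **not** emulate: irregular (non-elliptical) real
zone geometry, accretionary growth-axis anisotropy, vaterite patches,
beam-damage artifacts, detector dead time, or spatially correlated
spectral-fit residuals. Passing synthetic tests therefore demonstrates the
correctness of the estimators under the stated model, not performance on
adversarial real scans — the manual-override paths exist for those.

## Problem sizes and determinism

Recovery statistics use 50 seeded scans per preset in the test suite and
12 per preset in `scripts/acceptance.py` (a desk-scale cohort per
phenotype; one full scan analysis takes ≈ 0.5 s). All randomness flows
from explicit integer seeds: scenario seeds drive generation, and the
acceptance script derives per-scan seeds from its `--seed` argument.
Reports contain no timestamps and serialize with sorted keys, so re-runs
are byte-identical.

## Known limitations

- The radial method assumes zone boundaries scale with the local otolith
  radius and that the outline is star-convex around the core.
- The marine patch area under a hard threshold is a biased (eroded)
  estimate at high noise; counts are the reliable patch statistic.
- `z1_max`-based flags are sensitive to counting-noise extremes on raw
  pixel values; on very noisy maps consider a calibrated `estuarine_z1`
  margin or pre-smoothing.
- The published palette of the original false-colour rendering is not
  public; the default LUT is a 5-anchor linear approximation of the named
  red–yellow–brown–cyan–slate-grey progression.
- Fiji's 3-3-2 convention (high bits → red) is adopted, with channels
  rescaled to the full 8-bit range for visibility.
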