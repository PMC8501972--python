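# Methods

## The measurement model

Each field of view carries three channels: a nuclear stain (DAPI-like), the green
RNA-trap channel (EGFP-like), and the red protein-of-interest channel
(mCherry-like).  Per cell the pipeline computes four arithmetic means of pixel
intensities — green and red over the *anchor* region, green and red over the
*whole nucleus* — and the relative fluorescence

r = (Red_anchor − Red_nucleus) / (Green_anchor − Green_nucleus).

Two properties make this statistic robust and are enforced by tests:

- **Offset invariance.**  Any constant added to a channel (camera pedestal,
  uniform background) cancels in the differences, so no background subtraction is
  performed before measuring.
- **Mask-error cancellation.**  If the anchor mask is too large or slightly
  misplaced, the dilution it causes affects the red excess and the green excess by
  the same spatial factor, as long as the *same* masks are used in both channels —
  which they are.  The dominant residual bias is boundary contamination: pixels of
  the nucleus mask (or, for the rim geometry, of the anchor band itself) that fall
  outside the true nucleus mix background into the means with different contrasts
  in the two channels.  For interior anchors (spot, puncta) this is a few percent;
  for the nuclear rim, whose band hugs the boundary, simulations show an upward
  bias of order 10–15% on the recovered fold.  This is a property of the rim
  measurement itself, not of the implementation.

The reference region is the **whole nucleus including anchor pixels** ("whole" read
literally); the anchor-area fraction then enters both reference means and cancels
exactly in the ratio.  Ratios may be negative (a red dip at the anchor) and are
kept unclipped, since clipping would bias group means upward.

Normalization divides every cell's ratio by the **arithmetic mean** of the control
group's ratios (means, not medians, are used throughout the reporting), so the
control group's normalized mean is exactly 1 and other groups read as
fold-enrichment.  Normalization requires a control with at least 3 QC-passing
cells and a positive mean; anything else is a hard error rather than a silent NaN.

## Segmentation and anchor detection

Nuclei: Gaussian smoothing (σ = 2 px) → Otsu threshold → hole filling → border
clearing → connected components → area filter (defaults 300–8000 px²).  The steps
are the minimal deterministic realization of DAPI-based nucleus partitioning; Otsu
makes the result invariant to affine intensity transforms of the stain.  Touching
nuclei are not split (they merge and typically fail the area filter); this is a
deliberate non-goal.

Anchor, per nucleus, by geometry:

- `single_spot`: Laplacian-of-Gaussian blob detection over σ ∈ [0.6, 1.6] ×
  `spot_sigma_px` (default 3.5 px, i.e. expected radius ≈ 5 px), on intensities
  robustly z-scored against the nuclear median and MAD so detection is
  affine-invariant.  A blob is accepted only if its mean z-excess over the nuclear
  background exceeds `detect_snr` (default 3).  The maximum-LoG-response blob wins;
  ties break by integrated intensity, then lowest (row, col).  The anchor mask is
  the disk of the detected radius, intersected with the nucleus.  Cells with
  multiple green spots therefore contribute a single winner; cells with no
  detectable spot get an empty anchor and fail QC (`no_anchor`) rather than
  erroring.
- `multi_puncta`: all accepted blobs pooled into one mask — one value per cell, no
  per-punctum statistics.
- `nuclear_rim`: the nucleus minus its morphological erosion by `rim_band_px`
  (default 4 px); no intensity detection involved.  The whole-nucleus reference is
  carried over to the rim and puncta geometries by analogy with the spot assay.

Everything is deterministic; there are no stochastic steps in segmentation or
measurement.

## Quality control

Cells are rejected, with reason codes, when: the anchor mask is empty
(`no_anchor`); the green excess is at or below the denominator floor
(`weak_trap`) — the floor defaults to 5% of the cell's nucleus-wide green mean, a
relative rule that rejects untransfected or weak-trap cells without assuming
intensity units; or the nucleus area is out of bounds.  Kept + rejected always
partition the segmented cells, and the run log asserts the accounting.

## Statistics

Two-sample, two-sided, pooled-variance Student's t (df = n₁ + n₂ − 2), stars
`*`/`**`/`***` at p < 0.05/0.01/0.001, no multiple-testing correction — comparisons
are reported marginally, each non-control group against the designated control.  A
Welch variant exists behind the `stats.welch` config flag, off by default.  Group
summaries report arithmetic mean and sample SD (n − 1); SD for n = 1 is flagged
undefined (NaN), never reported as 0.

## The synthetic-data generator

`simulate_experiment` renders, per condition, ceil(n_cells / 4) fields of 256×256
px with up to 4 nuclei on a jittered grid (never touching each other or the image
border).  Per cell:

- nucleus: an ellipse, semi-axes uniform in 16–22 px (22–28 px for the
  chromocenter preset), random orientation; stain level 150 a.u. ± 15% per-cell
  jitter over background 1.
- green: diffuse nuclear level 60 a.u.; the anchor structure adds a flat excess of
  120 a.u.  Structures are a disk of radius 5 px (spot), 16–24 disks of radius
  2.5 px placed by rejection sampling without overlap (puncta), or the 4-px rim
  band.
- red: per-cell diffuse level d_r ~ LogNormal(median 80 a.u., σ = 0.3),
  emulating cell-to-cell expression variability of a transiently expressed
  protein; inside the anchor the red level is d_r × gain with
  gain = 1 + (g₀ − 1)·G, where g₀ = 1.15 is the nonspecific recruitment baseline
  (controls show a small positive signal, so control normalization is defined) and
  G is the condition's binding fold.
- camera: constant offset 100 a.u., shot noise as a Gaussian with variance =
  0.3 × signal (an exact-Poisson option exists), read noise SD 1.5 a.u.  An
  optional single Gaussian PSF blur (`psf_sigma_px`) is available but defaults to
  0; structures are hard-edged by default so the analytic ground truth below is
  exact.  `noise.enabled = False` removes offset, blur and noise entirely.

With these choices the closed-form per-cell expectation is

raw_ratio = d_r (gain − 1) / anchor_excess,

independent of the anchor-area fraction (it cancels), and the control-normalized
expectation equals **G exactly** — so presets encode published fold-changes
directly as G, doubling G doubles the expectation, and the per-cell log-normal
expression factor cancels from the normalized group mean in expectation.
`expected_raw_ratio` / `expected_normalized_value` expose these oracles; with noise
disabled the pipeline reproduces them to 1e-9 relative error, and the property is a
test.

### What the generator does and does not emulate

It reproduces the features the statistic relies on: diffuse backgrounds, expression
variability, a nonspecific baseline, anchor geometry, camera noise.  It does not
model optics beyond the optional single blur, chromatic misregistration,
cytoplasmic compartments, uneven illumination, clustered untransfected cells, or
correlated trap/protein expression.  Passing the recovery tests therefore shows the
pipeline is unbiased and well-calibrated *under its own assumptions*; it does not
certify performance on real microscopy pathologies.  The true noise and background
levels of the assay are unreported, so the preset noise parameters are plausible
defaults, not calibrated values.

## Figure-matched presets

Presets freeze the experimental designs of the published figures, with group sizes
taken from the figure legends and expected enrichment equal to the printed folds:
`F1_pp7_PCP` (single spot; −RNA n=23 control, +ms2 n=25, +ms2-pp7 n=24 at G=2,
+ms2-pp7m n=26), `F2_polyA_PABPC1` (single spot; n=27/28/27, mRNA mimic at G=2),
`F5_chromocenter_MCP` (multi-puncta; n=23/26, G=3), `F6_dCas13a_MCP` (single spot;
n=21/23/26, G=2), and `F5_laminB1_INM` (nuclear rim; n=21/24; no fold is published
for that panel, so its G=2 is a representative choice and the preset is used for
geometry coverage, not for recovery claims).  A `_null` suffix gives the matched
null preset (all G=1).

## Problem sizes and numerical choices

Recovery tests average three replicate simulated experiments per preset; the t-test
calibration runs 200 replicates of the two-group matched null; monotonicity uses
G ∈ {1, 1.5, 2, 3} at n=25 with two replicates.  These sizes make the whole suite
run in a few minutes while keeping Monte-Carlo error well inside the asserted
tolerances.  Blob detection crops to the nucleus bounding box, so its cost scales
with nucleus size rather than field size.  Denominator floors, empty anchors and
degenerate geometries (rim band ≥ nucleus minor semi-axis, puncta that cannot be
packed without overlap) are rejected with explicit errors rather than produced
silently.

## Known limitations

- Single 2D plane only; no z-stacks, time series, or proprietary formats.
- Touching nuclei are merged, not split.
- The rim geometry's boundary-contamination bias (above) is inherent to rim
  measurements at this resolution.
- Student's t on right-skewed per-cell ratios is slightly conservative at these
  group sizes (observed null rejection ≈ 2.5–5% at α = 0.05), consistent with the
  t-test's documented behavior under skew.
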