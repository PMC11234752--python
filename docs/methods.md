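# Methods

This note documents the models, corrections and numerical choices behind
`ibspec`, what the synthetic phantoms do and do not emulate, and the
design decisions taken where the procedure was genuinely open.

## Data model

A *dataset* is a set of co-acquired 2D channels at one illumination
wavenumber: Height and Deflection in the trace direction, IR Amplitude,
PLL Frequency and IR Phase in both trace and retrace. The canonical
acquisition geometry is a 10×10 or 20×20 µm field at 512×512 px
(20–40 nm/px); the geometry invariant `pixel_size_nm · width_px =
1000 · field_width_um` is enforced at construction. Pixel coordinates
are row-major with the origin at the top-left, and invalid pixels are
carried as explicit boolean validity masks, never as sentinels. Point
spectra span 800–1800 cm⁻¹ at 2 cm⁻¹ steps and are assumed already
normalised to the laser emission spectrum; each carries a location
category (IB, cytoplasm, or epoxy background) and session metadata,
because all spectral references are per measurement session. Data are
stored in a single-file HDF5 container (`/maps/<wn>/<channel>/<dir>`);
vendor binary formats are out of scope.

## Spectral chain

Processing order: **epoxy division** (pointwise by the session-average
BG spectrum; non-positive reference points are masked and counted), then
**min–max rescaling** so the minimum/maximum *within 1600–1800 cm⁻¹*
map to 0/1. The affine rescaling is applied to the whole spectrum using
the window extrema, so values outside the window may leave [0, 1]; a
spectrum constant in the window is rejected as degenerate. β-sheet
content is the trapezoidal integral over 1615–1635 cm⁻¹ on the native
grid, with band edges linearly interpolated so the integral always
covers the full 20 cm⁻¹ span (a constant-1 spectrum integrates exactly
to 20). Band intensities (e.g. "around 1628" or "around 1678 cm⁻¹") are
*means* over ±5 cm⁻¹ windows (endpoints inclusive) so values are
comparable across window widths; the integral-based and window-based
β-readouts are deliberately kept as two separate functions and are not
unified. Second derivatives use a Savitzky–Golay filter, default window
9 points (16 cm⁻¹) and cubic order — wide enough to suppress noise,
narrow enough to resolve amide-I sub-bands 10–20 cm⁻¹ wide; polynomial
inputs are differentiated exactly in the interior. The PLL summary of a
spectrum is the mean PLL frequency over 1600–1650 cm⁻¹ minus the
session epoxy PLL reference.

## Registration

The 1625 cm⁻¹ acquisition follows the 1650 cm⁻¹ one by tens of minutes;
stage drift translates the scene and, when the drift is nonconstant,
shears it. Registration estimates the alignment affine on the two
*height* maps (the most structure-rich, wavenumber-independent channel):

1. **Rigid stage** — for each rotation on a coarse grid (±3°, 1° steps),
   FFT phase correlation with 1/20-px subpixel upsampling proposes a
   translation; the candidate with the best normalized cross-correlation
   (NCC) wins. A translation estimate at the ±15 px search bound raises
   a warning.
2. **Affine stage** — Powell refinement of all six parameters of the
   NCC objective, initialized at the rigid optimum, with the linear part
   bounded to ±5% deviation from identity to exclude degenerate fits.
   The NCC is evaluated on a 20 px margin-cropped window so
   edge-resampling artifacts never enter the objective.

The final transform resamples every 1625 channel bilinearly;
out-of-frame pixels are masked. On noise-free phantoms with translations
≤10 px and shear ≤3% the mean residual displacement over the cell
support is below 0.1 px (acceptance bound: 0.5 px), and β-enrichment
estimated after registration is unbiased while the unregistered estimate
is biased low — misaligned ratio pixels mix IB numerators with
cytoplasm denominators.

## PLL line correction

The PLL pulse rate drifts slowly (thermal, cantilever) with an
additional per-line random component. The correction computes the mean
PLL over epoxy pixels line-by-line, smooths this profile with a centered
rolling mean (default 16 lines — long enough to suppress per-line noise,
short enough to track drift), and subtracts it from the whole map. Two
numerical details: lines without any epoxy pixel are filled by linear
interpolation from neighbouring lines (logged), and the profile is
padded by *linear extrapolation* (least-squares line over the edge
segment) before averaging, which keeps the correction exact for linear
drift at the map edges where a shrinking or reflected window would be
biased. Downstream per-IB summaries use the corrected **1650 cm⁻¹** PLL
map — the higher IR amplitude at 1650 cm⁻¹ makes its PLL tracking the
more reliable of the two. The rolling mean intentionally preserves the
per-line noise component; the acceptance check therefore bounds the
corrected per-line epoxy means by 3× the standard error implied by the
full noise model (per-line SD plus pixel SD/√n), allowing the expected
Gaussian tail across hundreds of lines.

## Segmentation

**Cells.** The backend contract is any callable mapping the 1625 cm⁻¹
IR amplitude image to an instance label map; a fine-tuned external model
(e.g. Cellpose) can be plugged in. The built-in fallback is Gaussian
smoothing (σ = 2 px) → global triangle threshold (cells are bright at
1625 cm⁻¹) → hole filling → a radius-2 opening that cuts smoothing
bridges between adjacent cells → distance-transform watershed with
markers at per-component EDT cores (> 0.5 × component maximum). Each
instance is then eroded by a 2 px disk (membrane discard), instances
touching the image border are removed, and labels are made contiguous.

**Triangle threshold.** Histogram of 64 bins over [min, max]; a line
runs from the histogram peak to the *farthest nonempty* bin (symmetric
rule — the side is whichever nonempty bin lies farther from the peak),
and the threshold is the center of the bin maximizing the perpendicular
distance between histogram and line. Index and count axes are
normalized first, making the construction equivariant under affine
rescaling of the intensities. The implementation is cross-checked
bin-exactly against an independent brute-force oracle.

**IBs.** Per cell, the interior intensities are triangle-thresholded
(cells with <16 interior pixels are skipped — too few for a histogram;
a pooled-across-cells mode exists for sensitivity analysis), the
supra-threshold mask is opened with a radius-2 disk, and pixels outside
the cell mask are discarded. The opening is what sets the detection
limit: a radius-1 disk contains no translate of the structuring element
and vanishes, while a radius-2 disk is itself the structuring element
and survives exactly — the smallest detectable IB has a 2 px radius
(40–80 nm depending on pixel size). One guard supplements the symmetric
tail rule: when the triangle threshold falls at or below the cell's
median intensity, the histogram is unimodal (the low-side tail happened
to be longer) and the cell is reported as IB-free; IBs are by definition
a bright minority population, so a threshold below the median cannot
describe one. Border-clipped IB components are kept.

## Features

Cell geometry comes from second moments (inertia tensor): centroid,
major-axis orientation (CCW from image x, y up, in (−π/2, π/2]), and
major length as the pixel-projection extent along the axis. Masks whose
principal moments differ by <2% are flagged orientation-degenerate.
The **polar position** of an IB is the signed projection of its centroid
offset on the major-axis unit vector, normalized by the half-length and
clipped to [−1, 1]; the axis vector is oriented so its image-x component
is positive, making the right-hand pole positive (the sign itself
carries no biology — pole age is not observable here). `pole_proximity`
is |polar_position| (1 = at a pole). The cytoplasm of a cell is its
eroded mask minus *all* of its IB pixels; a cell fully covered by IBs
has undefined enrichment and its records are flagged and excluded from
enrichment statistics. β-enrichment is a ratio of ratios and hence
invariant to global rescaling of either amplitude map. The thickness
proxy is the mean height over the IB minus the mean epoxy height.

Edge-distance profiles assign every pixel its signed Euclidean distance
to the nearest IB boundary (positive inside, computed from the distance
transforms of the mask and its complement, with a half-pixel shift
because the boundary lies between pixel centers), restrict outside
pixels to cell interiors, bin at 1 px by default, and report per-bin
means with percentile-bootstrap CIs. The boundary *transition width* is
defined on a fitted logistic as the central 95.4% span
(2·ln(1/0.02275 − 1)·scale), the quantile range equivalent to ±2σ of a
Gaussian edge whose conventional transition width is 4σ; on phantoms
with Gaussian edge blur σ = 1–2 px this recovers 4σ·pixel_size within a
few percent.

## Statistics

Group comparisons follow the pretest decision tree: Shapiro–Wilk per
group and Bartlett across groups choose between one-way ANOVA and
Kruskal–Wallis. The pretest level (default 0.05) is controlled
*family-wise*: each pretest p is compared to α/(n_groups + 1),
Bonferroni over the per-group Shapiro tests plus Bartlett. Without this
correction the parametric branch would be selected with probability
only ≈0.95⁴ ≈ 0.81 under a genuinely Gaussian null — an uncorrected
per-test rule misroutes a fifth of well-behaved data to the rank test;
with it, selection consistency is ≈1 − α while heavy-tailed data still
fail Shapiro at vanishing p. An uncorrected mode is available. Post
hocs: Tukey HSD (all pairs; reduces exactly to the pooled t-test for
two groups) or Dunnett (each group versus a control) after ANOVA, and
Dunn's rank test after Kruskal–Wallis (the follow-up is unstated in
common practice; Dunn is our choice and is labelled as such). Bonferroni
adjustment is **uncapped** by default — adjusted values above 1 are
reported as computed (e.g. p_adj = 2.2), which keeps the correction
count auditable; a capped mode exists, and every report records how many
corrections were applied so nothing is silently double-corrected.

Bootstrap CIs are percentile intervals (default n = 9999,
seed-deterministic); BCa was considered and rejected as unnecessary for
the mean-type statistics used here. The correlation analysis computes
Pearson r for every property pair *within* each dataset, then
bootstrap-resamples the resulting set of per-dataset correlations to
test the mean r against zero (two-sided percentile p with add-one
correction), Bonferroni-corrected over the number of property pairs.
Resampling the r-set (rather than IBs within datasets) treats the
dataset as the independent replication unit. Constant properties yield
undefined r for that dataset and are excluded from that pair's set.
PCA is mean-centered with a deterministic sign convention (the
largest-magnitude loading of each component is positive); 2D embeddings
are pluggable (UMAP with a fixed seed when installed, PCA, or any
callable).

## Synthetic phantoms

The phantom emulates what the pipeline must correct, not the underlying
photothermal physics. A scene is a flat epoxy background (amplitude 1.0
at both wavenumbers) with non-overlapping elliptical cells (major axis
2–3.5 µm, minor 0.8–1.3 µm, uniformly random orientation — the 2D
signature of randomly sectioned rods), each possibly containing disk
IBs planted at integer pixel centers so a radius-r disk is exactly the
r-ball of the pixel grid. Amplitude levels: cells 2.0 at 1650 cm⁻¹,
cytoplasm 1.6 at 1625 cm⁻¹ (ratio 0.8), IB 1625-amplitude =
enrichment × 1.6, so the planted ratio-of-ratios equals the enrichment
exactly. Defaults: enrichment 1.4, edge blur σ = 1 px, amplitude noise
SD 0.02 (SNR ≈ 30 on the cell contrast), inter-map drift (3, −2) px
with 1% shear, PLL offsets 0.15 kHz (cell) + 0.3 kHz (IB), per-line PLL
drift 0.002 kHz/line with 0.01 kHz line noise and 0.02 kHz pixel noise,
256×256 px over 10×10 µm (39 nm/px) — chosen to mirror a realistic
single-field acquisition while keeping every test fast. Drift is
applied to the (later) 1625 acquisition by resampling through the
inverse of the true alignment transform, which is recorded in the
ground truth. Trace and retrace copies carry independent noise. Cells
are placed with an enforced epoxy gap (≥8 px) and border margin so that
instance segmentation on the phantom is well-posed.

Deliberate simplifications: additive Gaussian noise (no 1/f scan noise,
no probe-shape convolution, no resonance physics), sharp cell borders,
constant within-class amplitudes, linear per-line drift. Consequently,
passing tests demonstrate the *correctness of the computational chain*
under its stated assumptions — unbiasedness of the enrichment estimator
after registration, calibration of the statistical layer — not
robustness to every instrumental artifact of real acquisitions.

Synthetic spectra are sums of Gaussian bands: helix/disordered 1654,
β-sheet 1628 (weak in cytoplasm, strong in IB presets), with peroxide
presets adding antiparallel (1678) and intermolecular (1616) β-bands.
The epoxy band list is illustrative and configurable — no measured
resin spectrum is claimed.

## Recovery experiments

The enrichment-recovery experiment (20 phantoms, true enrichment
1.0–2.0, noise-free, regression slope 1 ± 0.05) uses the phantom's
ground-truth label maps as segmentation input: at enrichment 1.0 IBs
have no intensity contrast and are invisible to any intensity-based
segmenter by construction, so the experiment isolates the feature
extraction (registration → ratio map → per-IB statistics) from the
detector. Detection itself is validated separately on contrasted
phantoms (exact per-cell counts; areas within the erosion–dilation
discretization envelope of the opening).

## Pipeline and reproducibility

`run_pipeline` executes simulate/load → QC → register → segment →
features → report from a TOML config; unknown sections or keys are
rejected before any computation, every defaulted parameter is logged
once, and the JSON report carries the package version, seed and a
config hash. The same config and seed reproduce byte-identical CSVs
(full-precision `%.17g` serialization; CSV import uses round-trip float
parsing). Problem sizes throughout the test suite (160–256 px scenes,
100–1500 simulation replicates, n_boot 9999 where the analysis
prescribes it) are chosen so the default suite completes in about a
minute on one core.

## Known limitations

* The symmetric triangle tail rule needs the median guard on unimodal
  histograms; a principled alternative would model the cell histogram as
  a mixture, at the cost of the algorithm's simplicity.
* Diffuse IB edges bias segmented areas up and mean enrichment down
  (halo pixels); this is a property of threshold segmentation on blurred
  objects, visible in the worked example, and is why boundary widths are
  quantified separately via edge-distance profiles.
* PLL-based stiffness contrast is relative only; no Young's modulus is
  derived.
* The fallback cell segmenter is tuned to phantom-like contrast; real
  maps with touching cells or strong knife marks will need an external
  instance-segmentation backend.
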