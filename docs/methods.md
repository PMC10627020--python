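# Methods

This note documents the models, parameter choices and numerical
conventions behind `boldkernel`, and what the synthetic validation does
and does not establish.

## Task design

`make_design(n_movement, n_rest, block_s)` builds a rest-first
alternating block design; rest counts must equal or exceed movement
counts by one. Defaults mirror the standard motor paradigm: 30 s blocks,
4 movement + 5 rest for the scanner run (270 s), 5 + 5 for the ECoG run
(300 s). Total duration is always the exact sum of block lengths.

## ECoG band response

* **Channel screening** is a single pass with leave-one-out reference
  statistics: channel *c* is rejected when its variance lies outside
  mean ± 3·SD of the variances of the *other* channels (sample SD).
  Leave-one-out prevents a single extreme channel from masking itself by
  inflating the reference spread. Screening precedes re-referencing.
* **Common average reference** subtracts the samplewise mean of the
  retained channels; it is idempotent and makes channel sums exactly zero.
* **Windows** are tiled from each block onset in non-overlapping 2 s
  steps; windows that would cross a block boundary or the end of the
  recording are dropped. 2 s at 512 Hz gives exactly 0.5 Hz PSD bins.
* **Band log power** is the mean of natural-log-transformed one-sided
  Hanning-tapered periodogram bins with f_lo ≤ f ≤ f_hi, both edges
  inclusive (61 bins for 65–95 Hz). Bins are floored at 1e-30 before the
  log, with a runtime warning — only degenerate synthetic inputs reach
  the floor. Mean removal per window is the only detrending.
* **Statistics.** The movement−rest difference is the classic pooled
  equal-variance two-sample *t* (df = n₁+n₂−2), computed in closed form;
  a Welch variant sits behind `equal_var=False`. The z-score is the
  standard-normal quantile at 1 − p/2 carrying the sign of *t*, capped at
  ±38 (the quantile overflows past ~37.5). Significance is the
  uncorrected two-sided p < 0.05 — the screen only selects electrodes for
  the correlation and is not itself an inferential endpoint.

## BOLD z-map

* **High-pass filter**: at every time point a straight line is fitted to
  the voxel series by weighted least squares with Gaussian weights
  (σ = 45 s) centred there, and the fitted value subtracted (series mean
  added back). The filter is a linear smoother; the operator matrix is
  built once per run length and applied to all voxels by one matrix
  product. Weights are truncated at the series bounds (only in-range
  samples enter each fit). On a 444-volume run at TR 0.608 s the filter
  removes a linear ramp to machine precision, passes a 30 s-period
  sinusoid with < 2% amplitude loss and suppresses a 300 s-period
  sinusoid by > 80%.
* **HRF**: double-gamma, gamma-density peak delay 6 s, undershoot delay
  16 s, undershoot ratio 1/6, length 32 s, normalised to unit sum. The
  regressor is the movement boxcar on a 10 ms grid convolved with this
  kernel, sampled at volume times, then mean-centred.
* **GLM**: per gray-matter voxel, OLS of the filtered series on
  [intercept, regressor]; t = β/SE with df = n_vols − 2, converted to z
  exactly as in the ECoG module. No prewhitening or motion regressors:
  inputs are assumed aligned and motion-corrected upstream, and the
  df ignores temporal autocorrelation — a documented simplification that
  leaves the GLM null exactly calibrated on white noise but
  anticonservative on strongly autocorrelated real data.
  Zero-variance voxels get z = 0; exact fits get the capped z.

## Kernel-width sweep

* **Weights**: wᵢ ∝ exp(−dᵢ²/2σ²) over gray-matter voxel centers, with
  world-mm distances; voxel index (i,j,k) maps through the affine to the
  voxel center (the NIfTI convention), no half-voxel shift. Exponents
  are shifted by the minimum squared distance before exponentiation so
  arbitrarily small σ degrade gracefully to the nearest-voxel limit.
* **Truncation**: voxels beyond `trunc_k`·σ are excluded and weights
  renormalised. The default is trunc_k = 7: a 3D Gaussian holds ~1.1e-3
  of its mass outside 4σ and ~7e-8 outside 6σ; at 7σ the truncated
  weighted average agrees with untruncated summation to ~1e-7 for
  realistic z magnitudes, at negligible cost. Brute-force summation is
  retained as the test oracle.
* **Correlation**: Pearson r across the fixed significant-electrode set
  (positive and negative responders alike), r² as explained variance,
  and the OLS slope of fMRI z on ECoG z. Spearman is available behind a
  flag for robustness checks. The electrode set is fixed across the
  whole sweep; electrodes without gray matter inside the truncation
  radius at the smallest σ are dropped up front with a warning.
* **Peak**: argmax of r²(σ); ties resolve to the smallest σ, and a peak
  at either end of the grid is flagged `peak_on_boundary` (a boundary
  argmax is censored, not estimated — group statistics exclude it).
* **Concavity**: central second differences of r²(σ) on the uniform
  grid; the σ at the most negative value, ties to the smallest σ. When
  the minimum is not below a numerical-noise floor (flat or linear
  curves), the point is reported missing rather than fabricated. The
  differencing stencil defaults to a 1 mm step (4 grid steps on the
  default 0.25 mm grid): second differences amplify curve microstructure
  as 1/h², and at h = 0.25 mm the trough locks onto sub-voxel
  discretization features of the weighted average rather than the
  millimetre-scale physiology the statistic is meant to measure. On a
  unit-spaced grid the stencil reduces to ordinary central differences.
  Both the grid spacing and the stencil step are configurable.
* **Default grid**: 1–20 mm in 0.25 mm steps (77 points).

## Synthetic data generator

The generator defines the study conditions under which the pipeline is
validated.

* **Geometry**: a flat gray-matter slab (8 mm thick, 4 mm isotropic
  voxels) with an 8×8 electrode grid at 10 mm pitch ~1.5 mm above it.
  Two deliberate sources of geometric realism: the grid is rotated
  in-plane by a seeded 5–40° relative to the voxel lattice (clinical
  grids are never scanner-axis aligned), and each electrode gets 1 mm-SD
  Gaussian localization jitter in all three axes (post-implant CT
  localization is accurate to a couple of millimetres). Without them,
  every electrode shares the same voxel-relative geometry and the
  r²(σ) curve develops a coherent single-voxel-to-multi-voxel kink that
  dominates its second derivative.
* **Activation field**: a sum of Gaussian foci (default two, width
  16 mm) at seeded gray-matter locations under the grid, normalised to
  max 1. The field is deliberately broader than the largest point spread
  swept (8 mm): when signal and noise share a spatial scale, smoothing
  cannot trade one against the other and no kernel width is
  identifiable.
* **ECoG**: per-channel 1/f Gaussian noise (slope 1.0, SD 40 µV). The
  spectrum is split by brick-wall masks into in-band and out-of-band
  components; during movement blocks the in-band component of band *b*
  is rescaled so band power is multiplied by exactly
  1 + effect_b·field(electrode). Default effects: HFB +1.0,
  alpha −0.7, beta −0.6 — chosen so simulated per-electrode z ranges
  match motor-task magnitudes (broadband maxima ~ +14, alpha/beta minima
  ~ −9 to −14, roughly half the electrodes significant).
* **BOLD**: baseline 100, activation amplitude 3 (3% signal change at
  field 1) times the HRF-convolved boxcar, with the amplitude map equal
  to the truth field blurred by σ_true. The blur is gray-matter
  restricted with per-source renormalised weights (each source voxel's
  mass is redistributed over gray matter), which conserves total field
  mass exactly and makes σ_true the recoverable quantity. Nuisances:
  hemodynamic noise (SD 3) and the linear-ramp and 120 s-cosine drift
  coefficient fields (amplitude 2) are all spatially smoothed by the
  same σ_true — the vascular point spread acts on every hemodynamic
  fluctuation, not only the evoked response — plus a small spatially
  white thermal term (SD 0.5; thermal noise is minor at 3T with 4 mm
  voxels). This structure is load-bearing: if the dominant noise were
  spatially white, voxel-averaging gains would concentrate at the
  first-few-voxels scale and the concavity width would sit at the
  discretization scale for every σ_true, making the point spread
  unrecoverable.
* Everything is deterministic given the seed; the ECoG and BOLD draws
  use independent streams derived from it.

### What the synthetic validation shows — and does not

Passing tests establish that the pipeline recovers the *direction* of
band couplings and, via the concavity statistic, orders and approximately
locates the ground-truth point spread (medians ≈ 2.3 / 3.8 / 9.2 mm for
σ_true = 2 / 4 / 8 mm over ten seeds each) under a geometry and noise
family chosen to be realistic but simple. Real recordings add cortical
folding (the analysis ignores sulcal boundaries), vascular structure,
motion residuals, autocorrelated fMRI noise with an uncharacterised
spectrum, epileptiform activity, and between-session state changes; none
of these are emulated, so the synthetic recovery bounds what the method
can do under favourable conditions rather than guaranteeing field
performance.

## Pipeline and group aggregation

Stages read and write a BIDS-like tree (`*_electrodes.tsv`,
`*_channels.tsv`, `*_events.tsv`, an ECoG sample matrix with a JSON
sidecar, BOLD and gray-matter mask NIfTIs with a shared affine —
mismatched affines are an error) and put derived outputs under
`derivatives/<subject>/`. Runs are idempotent and the effective
configuration is serialized alongside the outputs. A band with fewer
than three significant electrodes is marked skipped; other bands
complete. Group statistics use the sample (n−1) SD; subjects with a
boundary peak are excluded from peak statistics and subjects with a
missing concavity point from concavity statistics, with exclusion counts
reported. Histograms per band are written as PNGs.

## Problem sizes

Defaults throughout are the full study conditions (64 electrodes, 77
kernel widths, 444/~493-sample volumes and 150 ECoG windows per run).
The test suite simulates complete subjects at these defaults; the
multi-seed recovery experiments use ten seeds per condition, and the
acceptance script aggregates a five-subject group — sizes at which every
group-level quantity is stable to well within its across-seed spread.

## Known limitations

* The t→z mapping caps at ±38; perfectly noiseless fits are reported at
  the cap and flagged rather than infinite.
* GLM degrees of freedom ignore autocorrelation (see above).
* The concavity statistic is reported missing for curves with no
  downward concavity (e.g. monotone-convex r² curves); group summaries
  count these exclusions rather than imputing.
* Geodesic (surface-constrained) distances are not supported; distances
  are Euclidean in world mm.
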