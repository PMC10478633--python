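# Methods

This note documents the statistical model behind `rgfit`, the parameters
that matter, the synthetic studies the tests and `scripts/acceptance.py`
run, and the numerical and design choices made where more than one
reasonable option existed.

## Model and assumptions

A data set is assumed to contain one dominant *structure* — points
generated by a low-order geometric model (constant, line, or plane) plus
i.i.d. Gaussian noise of unknown scale σ — contaminated by outliers of
arbitrary distribution.  Two assumptions carry all the weight:

1. **Structure-size prior**: at least `likely_ratio` of the points belong to
   the structure (default 0.5), and at least `certain_ratio` of them are
   almost surely structure members (default 0.3).
2. **Separability**: an outlier is only detectable if it lies further than
   λσ from the structure (λ = 3 by default).  Contamination *inside* the λσ
   band is indistinguishable from noise by construction; the model fit
   resists it (see the trimmed step below) but the inlier segmentation will
   include it.

## The fitting pipeline

`flkos_fit` (and its wrappers `fit_value`, `fit_line`, `fit_plane`) runs:

1. **Guided-sampling iteration (FLkOS).**  Starting from a seeded random
   subset (or from `model_value_init`), each iteration least-squares-fits
   the current subset, computes all squared residuals, and takes as the next
   subset the points at residual ranks `(k−s, k]`, where
   `k = ⌈likely_ratio·N⌉` and `s = max(p+1, ⌈certain_ratio·N⌉)` capped at
   k.  The block *ends* at rank k so it stays inside the presumed structure.
   The iteration runs `opt_iters` times (default 12) with an early exit when
   a rank set repeats; the iterate with the smallest kth residual is kept.
2. **Trimmed refit.**  Ordinary least squares on the k points nearest the
   best iterate.  This is the natural least-kth-order-statistics output and
   is what protects the estimate when contamination overlaps the noise band:
   the k nearest points are structure members whenever the structure-size
   prior holds.
3. **Scale estimation (MSSE).**  The sorted squared residuals are
   accumulated; starting from `k_min` points the walk accepts point k+1
   while r²₍ₖ₊₁₎ ≤ λ²σₖ², σₖ² = Σ r²₍ⱼ₎/(k−p).  Inside the fitters the walk
   starts at `max(k_min, ⌈certain_ratio·N⌉)` rather than at the raw `k_min`:
   certain_ratio is by definition a lower bound on the structure size, and
   starting a 1000-point walk at k=12 occasionally (≈10⁻³ per call) stops
   spuriously because the scale accumulated from the 12 smallest residuals
   is unstable — on detector windows that collapse manufactured false peaks
   with SNR in the hundreds.  Direct `msse()` calls keep the documented
   k_min contract.
4. **Reweighted refit.**  Ordinary least squares on the points within λσ of
   the trimmed model, followed by a final MSSE pass.  The trimmed fit alone
   has the (low) efficiency of a 50%-coverage trimmed estimator; the
   reweighted step recovers near-full least-squares efficiency whenever the
   outliers are separable.  In `fit2skewed` mode this step is *skipped*: for
   skewed noise the symmetric λσ band is not a valid acceptance region (it
   would re-admit the heavy tail), so the trimmed fit stands.

Returned inlier flags are exactly the points whose absolute residual (after
the `minimum_residual` floor) is within `threshold = λ·σ` of the final
model, so flags, threshold and σ are always mutually consistent.

**Weighted MSSE.**  `msse_weighted` excludes zero-weight points outright and
uses the weight-scale-invariant recursion
σₖ² = (Σ_{j≤k} w r²₍ⱼ₎ / Σ_{j≤k} w) · k/(k−p), which reduces bit-exactly to
the unweighted walk for unit weights and is invariant to rescaling all
weights by a common factor.

**fit2skewed schedule.**  `certain_ratio` decays linearly from its starting
value to a 0.05 floor across the iterations, concentrating the final blocks
on a thin residual shell near rank k; suitable for unimodal skewed densities
(Gaussian ⊛ exponential, as from Poisson counting plus readout noise).

**median_of_fits** repeats `fit_value` (default 3 repeats; the first repeat
uses the caller's seed unchanged so one repeat equals one fit) and returns
the elementwise median of parameters and scale, with flags recomputed from
the median model.

## Parameters

| parameter | default | meaning |
|---|---|---|
| `lambda_cutoff` λ | 3.0 | Gaussian cutoff; inlier band is ±λσ. 2–4 is sensible (95% of a Gaussian within 2σ, 99% within 4σ). |
| `k_min` | 12 | unconditional acceptance count at the start of the MSSE walk |
| `minimum_residual` | 0 | floor on \|residual\| before squaring; set >0 on quantized integer images to avoid σ → 0 lock-in |
| `likely_ratio` | 0.5 | structure-size prior (fraction) |
| `certain_ratio` | 0.3 | almost-sure structure fraction; drives the sampling block and the MSSE walk start inside the fitters |
| `opt_iters` | 12 | FLkOS iteration budget |
| RPF `window` | 32 px | local background window of the peak finder |
| RPF/RMM `snr_threshold` | 6.0 | acceptance threshold on statistical separability |
| RMM `win` | 64 px | window of the mask maker's abnormality maps |
| `num_strides` | 1 | stride-shifted tilings per axis in `fit_background` |

The SNR is `(x_p − μ_B)/σ_B`, sign-preserving (deficient pixels get negative
SNR).  One published presentation of this quantity prints it as
(μ_B − x_p)/μ_B; that form is inconsistent with the way the threshold of 6
is used against peak SNRs in the same context, so the separability form
above is implemented.

## Background estimation

`fit_background` tiles the frame with `(win_y, win_x)` windows; each window
with at least `k_min + 1` valid pixels is fitted with a tiltable plane
(`num_model_params = 4`, i.e. three plane parameters plus the scale) or a
constant (`num_model_params = 1`).  Every covered pixel receives the model
*prediction* (so tilt is preserved per pixel) and the window's σ.  With
`num_strides = m`, the tiling is repeated at offsets `round(i·win/m)` per
axis (a clipped partial window covers the leading edge) and per-pixel values
are averaged over the m² tilings.  Windows too sparse to fit borrow the
model of the nearest fitted window of the same tiling; pixels never covered
or invalid carry NaN.

## Peak finder

1. *Candidates*: valid pixels that are strict maxima of their 3×3
   neighbourhood and exceed the median of their local region (implemented as
   the pixel's window-sized tile), ordered by intensity descending, capped
   at `max_peaks` (default 8192 — effectively uncapped at the frame sizes
   exercised here; a small cap is dangerous on tilted backgrounds because
   raw-intensity ordering favours the bright side of the frame).
2. *Evaluation*: a robust plane fit in the window centred on the candidate
   (clipped, not padded, at frame edges; discarded if fewer than `k_min+1`
   valid pixels remain); the candidate's SNR uses the plane prediction at
   the seed and the window σ.  A candidate at exactly the threshold is
   accepted (≥), so re-runs on quantized data are idempotent.
3. *Growth*: 4-connected flood fill from the seed over valid, unclaimed
   pixels above the local plane, confined to the seed's window.  Claimed
   pixels never join a second peak, so peak membership is a partition.
   The peak's centroid is excess-weighted; its intensity is the
   background-subtracted sum.

A frame is a hit when it has strictly more peaks than `min_peaks_for_hit`.

Fully valid frames take a vectorized fast path that evaluates all candidate
windows simultaneously (identical recursion, per-candidate seeds derived
from the base seed and the candidate's coordinates so results are
independent of evaluation order; the iteration's residual *ranking* is done
in single precision, scale estimation in double).  Masked or sub-window
frames use the per-candidate reference path; the two agree to ~10⁻⁵ in SNR
and are covered by a dedicated equivalence test.

## Mask maker

Per-pixel features of a calibration stack are deliberately **non-robust**
(defects must bias them): the registry ships `temporal_mean` and
`temporal_std`.  Each feature map is modelled as a constant per 64×64 window
with the robust machinery; the abnormality map is the per-pixel SNR of the
feature against its window model, sign preserved.  Thresholding is
two-sided (|SNR| ≥ threshold): dead pixels sit far *below* the mean model,
which is as abnormal as hot pixels sitting above it — they trip the mean
feature negatively and usually the std feature too (collapsed variance), so
they are identifiable from their code without a dedicated feature.  Bit i of
the 8-bit code marks feature i (at most 8 features); 0 is a good pixel.
The published pipeline this mirrors uses a larger, unenumerated feature set;
the registry is the extension point.

## Synthetic studies (what the tests and acceptance script run)

All generators draw from PCG64 under explicit seeds and return the planted
truth alongside the data.  Labels follow the generative recipe, not the
realized values, so an outlier drawn into the inlier band keeps its outlier
label — the irreducible label noise of recovery tests.

* **1D value**: n = 1000; separated contamination uses 70% N(10, 2²) + 30%
  uniform [40, 100]; the demo-style cloud uses inliers N(0, 0.5²) with
  outliers uniform [1.5, 6.5].  The inlier σ of 0.5 keeps the cloud starting
  3σ above the mean — the visibly separated regime the classic
  robust-vs-non-robust demos depict; with σ = 1 the cloud overlaps the λσ
  band and no band-based segmentation can exclude it (the model estimate
  still resists it via the trimmed step).
* **Line**: 1000 points, y = 2x + 1, vertical noise σ = 0.25, 30% box
  outliers.
* **Plane**: 32×32 grid, z = 0.1x + 0.2y + 50, σ = 2, 10% of pixels boosted
  by +40.
* **Diffraction frames**: 256×256, background 0.5·col + 0.25·row + 100,
  Gaussian noise σ = 3, ten 2-D Gaussian spots (width 1.5 px, amplitude
  30 = 10σ nominal SNR) placed with ≥ 24 px separation and ≥ 20 px margin.
* **Calibration stacks**: 512×512 × 100 frames, healthy pixels
  N(100, 5²); 30 hot pixels (+20σ mean offset), 10 dead (stuck at 0),
  20 flickering (5× noise).

Measured at these conditions (recomputed by `scripts/acceptance.py`):
parameter recovery within |bias| ≤ 0.3 and scale ±0.4 in ≥ 95% of seeds;
line/plane coefficients within ±0.05/±0.02 on every seed; mean-estimate
drift < 3 standard errors across a 0–45% outlier sweep; background-
normalized residuals with |mean| < 0.05 and std within [0.9, 1.1];
peak-finder precision = recall = 1.0 over 20 seeds with zero false peaks on
10⁶ pure-noise pixels; mask-maker precision and recall ≥ 0.98 over 20
seeds.

**What these fixtures do not emulate**: Poisson/gain detector response
(an optional Poisson toggle exists but the studies use Gaussian noise),
panel geometry and gaps, water/ice rings with curvature (backgrounds are
planes), peak shape anisotropy, and temporally correlated defects.  Passing
these studies shows the estimators do what they claim under their stated
assumptions, not that every real-detector pathology is handled.

## Numerical choices

* Residual sorting is stable; FLkOS subset selection uses partial
  partitioning (only the rank block and the kth value are needed), with
  ties broken arbitrarily but deterministically.
* The degrees-of-freedom denominator in σₖ² is k − p with p the fitted
  parameter count (1/2/3); k_min must exceed p.
* `minimum_residual` is applied as a floor on |r| before squaring, both in
  the MSSE walk and in the flag band.
* Degenerate designs (all x equal for a line; collinear support for a
  plane) raise immediately; subsets that turn singular mid-iteration fall
  back to a minimum-norm solve.
* All-zero residuals with a zero floor return σ = 0 with all points inliers
  (degenerate but valid).
* `ndarray.std` along the stack axis is avoided in feature computation (a
  two-pass per-frame accumulation is ~50× faster on this numpy for large
  stacks, with identical results at detector-count magnitudes).
* Every stochastic component takes an explicit seed; `find_peaks` derives a
  per-candidate seed from (base seed, row, col) so parallel and serial
  processing are bit-identical and candidate order is irrelevant.

## Known limitations

* Outliers inside the λσ band are segmented as inliers (separability
  limit); only the model estimate, not the flags, resists them.
* One structure per call: multi-structure data require fit-and-remove by
  the caller.
* The background model is a plane per window; strong within-window
  curvature (tight ice rings at small windows) biases the local fit.
* The peak growth rule ("above the local background") admits noise pixels
  adjacent to a peak (about half of the neighbourhood exceeds the
  background), so grown regions are larger than the optical spot and
  centroids carry ~1–2 px of noise-induced drift at SNR 10.
* The mask maker assumes flat-field statistics within a window; real gain
  gradients steeper than ~1 scale unit per window would need either smaller
  windows or a detrending feature.
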