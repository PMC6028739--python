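# Methods

This note documents the models, parameter choices and numerical decisions
behind each analysis stage, what the synthetic generators do and do not
emulate, and the known limitations.

## Shearlet transform

The transform is a finite discrete, cone-adapted construction evaluated in
the Fourier domain.  Radial Meyer-type windows partition frequencies into a
low-pass disc and `n_scales` bands whose widths halve per scale down from
the Nyquist band (the finest band saturates to the grid corners so coverage
is complete for any image size).  Within each band at scale *j* the shear
coordinate s = ω₂/ω₁ (horizontal cone, |ω₂| ≤ |ω₁|) or ω₁/ω₂ (vertical
cone) is windowed by Meyer bumps at integer shifts k ∈ [−2ʲ, 2ʲ]; the two
seam windows on the diagonals are glued across the cones and counted once,
giving 2^(j+2) orientation bands per scale and 1 + Σⱼ 2^(j+2) bands overall
(29 at the default 3 scales).

Two numerical choices matter:

- **Exact Parseval normalization.** The assembled window stack is divided
  by √(Σ_k W_k²) on the discrete grid, so the tight-frame identity and the
  adjoint reconstruction hold to machine precision for any (size, scales)
  combination — analytic tightness would hold only for scale counts matched
  to the grid.
- **Nyquist symmetrization.** On an even grid the ±Nyquist frequencies
  share one bin, which flips the shear coordinate along that row/column;
  squared windows are averaged with their mirror under frequency negation,
  restoring W(−ω) = W(ω) exactly so real images give real coefficients.

The transform is linear and translation-covariant (periodic boundaries);
non-square inputs must be padded or cropped upstream (the pipeline crops the
max projection to the nearest even square).

## Feature density and entropy–complexity plane

Per-pixel band powers E_k are squared coefficients, divided by the band's
spectral area, and smoothed with a Gaussian of scale-dependent width.  The
area calibration makes a flat-spectrum (white-noise) input produce equal
expected power in every band; without it the density mirrors band
bandwidths, not image content.  The smoothing default is σ = 24 px at the
coarsest scale, halved per scale: the coarsest band's coefficient field
decorrelates over ~16 px, and kernels much narrower than that average too
few independent samples, leaving spurious structure (white-noise densities
then sit ~0.2 total-variation away from uniform instead of < 0.1).

The density excludes the low-pass band by default (it encodes local offset,
not oriented structure; configurable).  Pixels whose total band power falls
below 10⁻¹² of the image mean power take the uniform density and are
flagged — the normalization is undefined at a zero denominator.

Entropies are in bits.  The entropy maximum is log₂N for N features; the
Jensen–Shannon normalizer J_max is evaluated in closed form at a degenerate
distribution (mixture entries (1 + 1/N)/2 and 1/(2N)).  Complexity is the
product C = Q_JS·H_s, zero at both the uniform and the degenerate limits.
Cell summaries are mask means by default (median available).

## Morphometry

Branch masks: per-plane Perona–Malik diffusion (10 iterations, exponential
conduction with the scale set at the 90th percentile of the initial
gradient magnitude, dt = 0.15), max projection, local-mean threshold in a
31 px window offset by 5 % of the intensity range (so flat regions —
background and sub-resolution leaflet haze — fall below threshold), removal
of objects under 16 px, and hole filling (the uniformly bright soma
interior otherwise thresholds hollow).

Sholl profiles sample each circle densely in angle (≥ 4πr points), merge
consecutive duplicate pixels, and count background→foreground transitions
with circular wrap-around; a circle fully inside foreground counts one.
The soma boundary is the first radius whose circle is not fully contained
in the soma's connected component; primary-branch and peak counts are read
from one radius step further out, because the circle at the boundary radius
itself rides the jagged thresholded soma edge.  Distal counts are the
profile beyond its peak.  Step default 2 μm.

Volume fraction: GV = (F − F₀)/(F_max − F₀) along a 45 μm line (length
checked to ±1 μm unless disabled), with F_max the soma-ROI mean and F₀ the
background-ROI mean; degenerate calibration (F_max ≤ F₀) and soma
saturation are errors.  GV is clipped to [0, 1] with the clip count
reported.  The leaflet mean excludes the initial soma run (GV ≥ 0.5) and
any user-marked branch intervals.  The measure is invariant to affine
intensity rescaling.

## Coupling

Records carry 3D Euclidean centroid distances under anisotropic voxel
calibration and ROI-mean intensities normalized to the patched soma.  The
length constant is −1/slope of the least-squares line on (d, ln I) —
matching the semilog convention used for reported values — with r² and an
invalid flag for non-decaying fits; a direct nonlinear fit is available.
The patched cell itself is excluded from the fit (configurable).

## Ca²⁺ events

Dark noise: per-pixel median of the dark frames, subtracted, negatives
clipped (counted).  Registration: single-step DFT phase correlation
(subpixel at 10× upsampling) against the first frame, applied with bilinear
interpolation.  Denoising is a pluggable hook (identity default; Gaussian
option); block-matching denoisers are deliberately out of scope.

Baseline: per pixel, a 60 s window, 3rd-order Savitzky–Golay smooth gives a
rough baseline; provisional ΔF/F above 2.5 robust SDs (1.4826·MAD) flags
transients; the flag mask is morphologically closed along time over the
window length (the rough baseline tracks the middle of transients wider
than about half the window, which would otherwise unflag their interior);
flagged samples are linearly interpolated and a 100 s filter yields the
final baseline F₀ and ΔF/F = (F − F₀)/F₀.  Window lengths convert from
seconds to odd frame counts at the calibrated frame interval.

Detection binarizes ΔF/F at k = 2.5 robust noise SDs per pixel (the
threshold scale is explicit configuration — a "statistical threshold" has
no unique magnitude), groups active pixels with 8-connectivity per frame
and links consecutive frames that share at least one footprint pixel (no
diagonal links in time; an optional gap tolerance can bridge silent
frames).  S_max is the area of the union-over-time footprint (the maximal
projection; the largest single-frame area is derivable from the voxel
lists); the integral is voxel count × pixel area × frame interval.
Exclusion filters are strict "less than": integral < 4 μm²·s, S_max
< 10 μm², duration < 2 s; boundary values are kept.

Power-law exponents come from least squares on log-binned densities
(12 bins per decade): the fitted range is capped at the sample's 99th
percentile and bins with fewer than 5 counts are dropped, because singleton
tail bins (with empty ones removed) otherwise flatten the slope; the
regression is weighted by the Poisson variance of each bin's log density,
which also gives a calibrated standard error.  Over 50 seeds at n = 10⁴ the
standardized errors for α ∈ {2.0, 2.7, 3.5} are approximately N(−0.3, 1).

## Electrophysiology

I_K is read 200 ms post-stimulus — past the fast field-potential and
transporter currents, which end within ~100 ms — and the decay from that
point is fitted with a mono-exponential (nonlinear least squares
initialized from the semilog line; span 2 s or trace end).  The
fifth-stimulus current is the pointwise 5-stimulus minus 4-stimulus
response.  fEPSPs are negative-going; sweeps are referenced to the
pre-stimulus mean, the fiber volley is the first fast negative peak within
2 ms of the stimulus, the fEPSP peak is sought in the following 40 ms, and
the 20–80 % rising slope uses linearly interpolated level crossings.  PPR
is the second over first amplitude at the 50 ms interstimulus interval.
The Gompertz fit y = a·exp(−exp(−k(x − x_c))) is initialized with
a = max(y), x_c at half-maximum and k from the finite-difference maximum
slope; its maximum slope a·k/e is exact in the fitted parameters.  LTP
magnitude averages the rising slope 47–60 min post-induction over a
≥ 20 min baseline.

## Synthetic generators

All generators are pure functions of (params, seed) and return exact truth
records.  Calibration defaults follow the study conditions: 0.5 μm/px, one
frame per second, 10 min movies with 30 dark frames, event floors at
10 μm² and 2 s (so the exclusion filters do not truncate the planted
power laws), 50 ms paired pulses, 5 kHz trace sampling.

- **Textures** — oriented single-frequency stripes, a recursive random tree
  blurred by a Gaussian point-spread kernel, and i.i.d. noise; they anchor
  the low/low, intermediate/high and high/low corners of the
  entropy–complexity plane.
- **Astrocytes** — bright soma disc, straight (optionally curved) rays, and
  a uniform haze at the planted volume fraction inside the cell domain;
  additive Gaussian noise.  Real arbors branch, taper and vary in
  intensity; passing tests show geometric correctness of the measurements,
  not robustness to biological morphology.
- **Ca²⁺ movies** — ellipse-footprint events with power-law areas and
  durations sampled by inverse CDF above the filter floors; amplitudes near
  1.2 ΔF/F held for the planted duration (1-frame rise, fast exponential
  tail — the plateau makes the planted duration the supra-threshold
  duration, i.e. recoverable), on a ±10 % multiplicative sinusoidal drift
  with shot-like noise and a constant dark offset.  Photobleaching, neuronal
  transients and event propagation are not modelled.
- **Coupling** — distances uniform on 10–120 μm, intensities
  I₀e^(−d/C_λ) with multiplicative lognormal noise.
- **Traces** — planted τ, amplitude ratios, Gompertz parameters and LTP
  profiles (constant, or exponential decay between stated early and late
  levels with a closed-form window mean for verification).

Noise models (additive Gaussian for imaging, lognormal for coupling) are
conventions, not reproductions — no acquisition noise statistics were
available to match.

## Problem sizes

Default analysis and test sizes are chosen for seconds-scale runs on one
CPU: 256² texture images, ~200² astrocyte planes, 100×100 px movies of
600 frames (50 μm/300-frame variants in the recovery suites), 10⁴-sample
exponent fits, 200-seed coupling noise sweeps.  All scale linearly with
image area and frame count.

## Known limitations

- The shearlet family is bandlimited Meyer-type only; no compactly
  supported variant, no 3D transform.
- Entropy/complexity values depend on the band layout and the smoothing
  widths; comparisons are meaningful within one configuration
  (the configuration hash is embedded in outputs for exactly this reason).
- Event linking has no diagonal-in-time connectivity and no splitting of
  merged events; heavily overlapping activity undercounts events.
- The log-binned exponent estimator carries a small negative bias
  (≈ 0.3 standard errors at n = 10⁴) inherent to fitting log densities of
  finite counts; the maximum-likelihood (Hill) estimator would be more
  efficient but the binned fit is retained as the field's convention for
  these data.
- Group-level statistics (Mann–Whitney, ANOVA) are intentionally absent;
  the pipeline emits tidy per-sample tables for standard tooling.
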