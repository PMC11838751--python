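# Methods

This note documents the models, defaults and design decisions behind
`shellmea`: what the synthetic generator simulates (and deliberately does
not), how each analysis stage works, and where the design was genuinely
open and a choice had to be made.

## The measurement being modeled

A shell MEA is a self-folding 16-electrode cage conforming to a roughly
spherical cardiac organoid (radius ~250 µm here). Each electrode records a
unipolar extracellular field potential at 30 kHz. When a beat propagates
over the organoid, electrodes activate in sequence; the *local activation
time* (LAT) under an electrode is marked by the steepest negative deflection
of its field potential. From 16 LATs one can interpolate an isochrone map
over the whole sphere and differentiate it into a conduction-velocity (CV)
vector field. A transparent device additionally permits calcium imaging of
the visible hemisphere, giving an independent optical activation map to
compare against.

## Synthetic ground truth (`shellmea.synth`)

No recordings of this geometry are publicly deposited, so the package ships
a generator that creates the entire study in silico with known ground truth.

**Wavefront.** A single focal origin on the sphere; the activation time of a
surface point is its great-circle distance from the origin divided by a
constant speed `v`. Defaults: `v = 5 cm/s`, sphere radius `r = 0.025 cm`,
beat period 1.25 s (48 bpm), so the maximal single-beat latency is
`π r / v ≈ 15.7 ms`. The focal origin is an explicit modeling assumption —
real organoids may have several or moving sources. The default origin
(−32.6° latitude, +185.2° longitude) is a generic point chosen once so that
all 16 default electrodes have distinct, well-separated true LATs (minimum
gap 0.58 ms); an origin on a symmetry plane of the layout would create exact
LAT ties, for which activation order is undefined.

**Unipolar waveform morphology.** The depolarization complex is built from
its slope: `dV/dt = −D(t) + p·R(t + 3σ) + q·R(t − 3σ)`, where `D` and `R`
are equal-area Gaussian humps of width `σ = depol_width/4` and the split
`p = (1 + β)/2`, `q = 1 − p` is set by the biphasic balance
`β = 2f − 1 ∈ [−1, 1]` with `f` the fraction of tissue already activated at
wavefront arrival (`f = (1 − cos θ)/2` for geodesic angle `θ`). Integrating
gives a wave that rises by `p·A`, falls by `A` through a smooth downstroke
centered exactly on the true LAT, and recovers by `q·A`:

* at the origin (`f = 0`) the deflection is purely negative (QS-like),
* mid-path (`f = 0.5`) symmetric biphasic (RS-like),
* at the last-activated point purely positive (R-like),

with peak-to-peak amplitude exactly `A` for every morphology (the complex is
renormalized numerically against lobe overlap). Two properties were designed
in deliberately: the slope minimum sits at the bottom of a smooth, locally
even dip, so zero-phase low-pass filtering does not displace it (the
measured residual LAT bias of the full chain is < 0.05 ms); and the default
width (`depol_width = 2 ms`) keeps the complex inside the 1000 Hz analysis
passband, matching the regime in which that filter leaves the waveform
essentially unaltered.

**Repolarization.** A low Gaussian hump (default +40 µV, σ = 25 ms) centered
`fpd_true` (default 300 ms) after each LAT, giving FPD detection a
well-defined target. Sign configurable.

**Noise.** White Gaussian noise at the acquisition rate plus a common-phase
60 Hz line sinusoid. "SNR" throughout means peak-to-peak depolarization
amplitude divided by the injected white σ at 30 kHz — a *raw-recording* SNR;
band-limiting during preprocessing raises the effective in-band SNR by about
√(15 kHz / 1 kHz) ≈ 3.9, just as it does for real recordings. All
randomness flows from one seed through spawned per-channel substreams, so
identical configurations are bit-reproducible.

**Drug effects.** Multiplicative factors on beat rate (period divided),
amplitude, FPD and conduction speed; nothing else changes.

**Calcium movies.** The visible hemisphere is orthographically projected to
the image plane (upper view = +x right; lower view mirrors x, as an
inverted microscope sees it). Each in-organoid pixel follows
`baseline + amplitude · logistic((t − LAT)/τ_r) · exp(−max(t − LAT, 0)/τ_d)`
with the logistic scaled so the 10–90% rise takes `rise_time` (default
40 ms) and half-maximum is crossed at the pixel's true LAT; decay constant
400 ms; optional Gaussian photon noise and electrode-occlusion masks.

**What the generator does not emulate** — and hence what passing tests do
*not* demonstrate about real data: multiple or migrating foci, reentry and
fibrillation, conduction anisotropy or heterogeneity, electrode drift and
motion artifacts, non-spherical geometry, photobleaching, optical blur and
depth-weighted fluorescence, and beat-rate variability. Results on real
organoids will degrade in proportion to how strongly these are present.

## Preprocessing (`shellmea.sigproc`)

30 kHz → 10 kHz by anti-alias filtering (8th-order Butterworth at 0.8× the
new Nyquist) and decimation (`ceil(n/3)` samples), then a 4th-order
Butterworth low-pass (default 1000 Hz; 100 Hz is the documented alternative
for badly contaminated recordings) and a Q = 30 IIR notch at 60 Hz.
Everything runs forward–backward (`sosfiltfilt`) by default: causal filters
would delay LATs and corrupt activation ordering. Non-integer rate ratios
fall back to polyphase resampling. SNR = (max − min over beat windows) /
(std of the complement); fewer than 100 noise samples or zero noise σ are
errors.

## Beat and LAT detection (`shellmea.activation`)

The NEO is computed per channel and summed across channels; beats are
detected on this aggregate so all 16 channels share one set of beat anchors.
Two practical guards, both standard in QRS-detector design: the detection
path (only) is high-passed at 30 Hz so slow repolarization waves contribute
no NEO cross-term energy, and the first/last 100 ms are excluded as
zero-phase filter settling. The threshold is `median + k·MAD/0.6745` with
`k = 8` by default, plus a floor of 1% of the NEO peak: on (near-)noiseless
traces the MAD collapses and the floor alone separates depolarization energy
(~6 orders above repolarization NEO) from the rest. Note the NEO of pure
Gaussian noise is heavy-tailed: on an *event-free* trace `k = 8` will fire
(k ≳ 30 is needed for a clean pure-noise trace), which is why thresholds
remain per-recording, auditable parameters rather than constants.

Within each window the slope LAT is the earliest interior minimum of the
central-difference derivative, refined to sub-sample precision by a
parabolic fit of the three samples around the minimum; a perfectly flat
window is a documented error. The amplitude LAT is the extremum of |x| (ties
break earliest). The activation order's reference ranking comes from the
per-channel mean LATs; accuracy is the fraction of (electrode, beat) pairs
whose per-beat rank matches the reference — the paper-style confusion matrix
holds the full rank frequencies. Beats missing any channel are excluded and
logged.

## Waveform metrics (`shellmea.fpmetrics`)

Beat rate is 60 / mean inter-LAT interval. Amplitude and FPD are measured on
the *beat-ensemble average* of each channel: beats are aligned at their
detected LATs, realigned by cross-correlation against the first-pass
template (sub-sample, ±2 ms search), and averaged. Two noise pathologies
motivated this: per-beat max/min estimates are biased upward by
extreme-value statistics, and residual LAT jitter smears a plain average,
biasing amplitude downward. Amplitude is peak-to-peak within ±25 ms of the
LAT (the depolarization spike, not the repolarization wave). FPD is the time
from LAT to the dominant |extremum| in `(LAT + 50 ms, next beat − 50 ms]`,
after low-passing the search segment at 30 Hz — the repolarization wave
lives below ~20 Hz, and an unsmoothed extremum under broadband noise is a
noise peak. The dominant-extremum rule (not the first local extremum) is a
deliberate disambiguation; both the blanking and the cutoff are
configurable. Per-beat (non-ensemble) metrics remain available. Drug
responses report per-channel `(post − pre)/pre × 100` with cross-channel
mean ± SEM and a paired t-test p-value as standard reporting plumbing.

## Spherical mapping and CV (`shellmea.spheremap`)

Distances are haversine great-circle distances; the kernel is the inverse
quadratic `1/(1 + (d/ε)²)` with default `ε` = mean nearest-neighbor
electrode spacing (~0.02 cm for the default layout). Two evaluation schemes
coexist:

* **Normalized weighted mean** (`interpolate_lat`): `Σ wᵢ LATᵢ / Σ wᵢ`.
  Every value is a convex combination of the electrode LATs — robust and
  bounded — but the surface does not pass through the electrode values and
  its gradients are systematically compressed. Measured on the 5 cm/s
  synthetic wave, inverse-gradient speeds from this scheme are inflated by
  ~30% at the smallest useful ε and ~130% at ε = nearest-neighbor spacing,
  monotonically in ε: the bias is structural and cannot be tuned away.
* **Exact interpolation** (`rbf_exact`, the default in `build_isochrone` and
  `project_hemisphere`): solve `K c = LAT − mean(LAT)` on the 16×16 kernel
  matrix and evaluate `mean + Σ cᵢ K(dᵢ)`. The surface honors every
  electrode LAT, reproduces constants exactly, and recovers the synthetic
  wave's speed to < 1% (median) with a coefficient of variation ≈ 0.1.

CV estimation therefore uses the exact scheme. It is worth recording that
the ~2.3× speed inflation of the weighted-mean scheme at ε ≈ electrode
spacing is the same order as published gaps between 3D-map CVs and optical
CVs for this kind of preparation — a reason to treat smoother-derived speed
maps with suspicion. With noisy LATs the exact interpolant fits the noise
exactly; the smoother can be preferable for visualization.

Gradients are central differences on a regular latitude–longitude grid
(default 64×128, poles excluded by half-step offset): east spacing
`r·cos φ·Δλ` (the metric factor is applied by default and can be disabled),
north spacing `r·Δφ`; longitude wraps, the top/bottom rows use one-sided
differences. Direction = normalized gradient; speed = 1/‖∇LAT‖ (Eq.-style
normalization defines only the direction — the inverse-magnitude speed rule
is this package's choice, consistent with reporting CV in cm/s). Nodes with
‖∇‖ below 1 ms per half-circumference (configurable) are masked invalid; a
constant map masks everywhere, with a warning rather than an error. Maps and
CV fields export as legacy-VTK ASCII polydata (points, quads, `LAT` scalars,
`speed` scalars, tangent `CV` vectors); the writer is self-contained and a
minimal reader exists for round-trip tests. A three-point circumradius
utility supports the device-folding curvature measurement.

## Calcium pipeline (`shellmea.calcium`)

Mask: per-pixel temporal dynamic range above 20% of the field maximum
(configurable; 0 keeps the whole non-occluded field of view), minus
electrode-occlusion geometry; an all-flat movie is an error. Traces are 3×3
local spatial means; baseline is the 10th percentile of each trace (the
half-maximum rule needs a baseline the source text does not define); the LAT
is the first crossing of baseline + half the dynamic range, linearly
interpolated between frames — gain- and offset-invariant by construction.
5×5 non-overlapping max pooling follows (output `ceil(n/5)`, pixel pitch
×5); max pooling biases each window toward its *latest* activation, so mean
pooling is available behind a flag. Smoothing fits
`T = a + bx + cy + dx² + exy + fy²` by least squares over a 600 µm window
around each pooled pixel (≥ 6 valid points required) and takes the fitted
`a` — the surface value at the window center — as the smoothed LAT. Planar
CV uses central differences over the physical pooled-pixel pitch; a pixel
needs itself and its four neighbors valid and a gradient above threshold.

## Cross-modality comparison (`shellmea.compare`)

The hemisphere projection re-interpolates from the 12 electrodes a
microscope could corroborate (8 equatorial + 4 polar-ring) and evaluates the
interpolant analytically at each pixel's back-projected surface point — an
analytic replacement for rendering screenshots and decoding colors, which
adds no renderer round-trip error but produces the same map content. Maps
are compared over co-valid pixels by Pearson r and MAE as a percentage of
the *reference* map's LAT range (the normalization is stated explicitly
because it is a reporting convention, not a given); `zero_align` subtracts
each map's co-valid minimum first, since different modalities carry
unrelated absolute time origins. CV fields are compared through their
valid-speed distributions (n, mean, median, quartiles).

## Problem sizes and tolerances used in validation

The test suite and `scripts/acceptance.py` validate on: 60 s recordings at
30 kHz (16 channels) for LAT/ordering recovery; 8–41 s recordings for the
method comparisons and metric recovery; 20 independent noisy runs for the
slope-vs-amplitude ordering comparison; 100×100-pixel movies at 60 Hz for
the optical pipeline; a 64×128 sphere grid for CV. These sizes were chosen
as the smallest at which the estimators' statistical errors are clearly
below the documented tolerances (e.g. mean-LAT error < 0.5 ms, CV median
within 10%, optical CV within 15%, drug factors within 5%); larger runs
change nothing qualitatively. Key numerical choices: sub-sample parabolic
refinement of slope minima; MAD-based robust scales; `arcsin` arguments
clipped against rounding for antipodal points; kernel systems solved
directly (16×16, condition number ~20 at the default ε).

## Known limitations

* The focal, constant-speed wavefront is the strongest assumption; the CV
  pipeline reports apparent speeds for any LAT field but its validation is
  against this model only.
* Exact RBF interpolation of *noisy* LATs transfers LAT noise into the CV
  field; no regularized middle ground between "exact" and "smoother" is
  implemented.
* Max pooling's late-activation bias propagates into the optical maps
  (documented, default kept for fidelity to the established procedure).
* The beat detector assumes a shared beat across channels (organoid-scale
  synchrony); dissociated or fibrillating preparations violate this.
* 2D projection comparison assumes perfect registration (same center, scale
  and orientation); no image registration is attempted.
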