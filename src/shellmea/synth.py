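"""Synthetic shell-MEA recordings and calcium movies with known ground truth.

No organoid recordings are publicly deposited, so every downstream stage of
the pipeline is exercised against this generator.  The model is deliberately
phenomenological, not biophysical:

* a focal activation wavefront expands at constant speed ``v`` from a single
  origin over a sphere of radius ``r``; the true activation time of a surface
  point is its great-circle distance from the origin divided by ``v``, so the
  maximum single-beat latency is ``pi * r / v``;
* each electrode sees one unipolar depolarization complex per beat whose
  morphology depends on how much tissue has already activated when the
  wavefront arrives: purely negative at the origin (all tissue still at
  rest), symmetric biphasic halfway, purely positive at the last-activated
  point.  The complex is built so its steepest negative slope falls exactly
  at the true activation time, which is the physiological anchor that
  slope-based LAT detection exploits;
* a low, wide repolarization hump follows each activation at the configured
  field-potential duration (FPD), giving FPD detection a defined target;
* white noise plus 60 Hz line interference emulate the disturbances the
  preprocessing chain is designed to remove;
* matched fluorescence movies render the visible hemisphere orthographically
  with a sigmoidal calcium upstroke at each pixel's projected activation
  time.

All randomness flows through one seed; per-channel noise uses spawned
substreams, so identical configurations reproduce outputs bit for bit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .sigproc import MultichannelRecording
from .spheremap import ElectrodeLayout, haversine, orthographic_grid

__all__ = [
    "WavefrontModel",
    "WaveformTemplate",
    "NoiseModel",
    "CalciumImagingConfig",
    "FrameStack",
    "true_activation_time",
    "activated_fraction",
    "simulate_recording",
    "simulate_calcium_movie",
    "render_movie",
    "planar_wave_lat_image",
    "apply_drug_effect",
    "sigma_for_snr",
]

# default focal origin: a generic point chosen so all 16 default-layout
# electrodes have distinct, well-separated geodesic distances (no layout
# symmetry plane passes through it)
DEFAULT_ORIGIN_LAT = math.radians(-32.6)
DEFAULT_ORIGIN_LON = math.radians(185.2)


@dataclass(frozen=True)
class WavefrontModel:
    """Constant-speed geodesic expansion from one focal origin."""

    origin_lat: float = DEFAULT_ORIGIN_LAT    # radians
    origin_lon: float = DEFAULT_ORIGIN_LON    # radians
    speed: float = 5.0                        # cm/s
    sphere_radius: float = 0.025              # cm (250 um)
    beat_period: float = 1.25                 # s  (48 bpm)
    n_beats: int = 8

    def __post_init__(self):
        if not (self.speed > 0):
            raise ValueError("wavefront speed must be > 0")
        if not (self.sphere_radius > 0):
            raise ValueError("sphere radius must be > 0")
        if not (self.beat_period > 0):
            raise ValueError("beat period must be > 0")
        if self.n_beats < 1:
            raise ValueError("n_beats must be >= 1")

    @property
    def max_latency(self) -> float:
        """Largest single-beat activation delay: pi * r / speed (s)."""
        return math.pi * self.sphere_radius / self.speed


def true_activation_time(phi, lam, model: WavefrontModel, beat: int = 0):
    """Ground-truth activation time of sphere point(s) for one beat (s)."""
    d = haversine(phi, lam, model.origin_lat, model.origin_lon,
                  model.sphere_radius)
    return d / model.speed + beat * model.beat_period


def activated_fraction(phi, lam, model: WavefrontModel):
    """Fraction of the sphere surface already activated when the wavefront
    reaches the given point: (1 - cos(theta)) / 2 for geodesic angle theta."""
    d = haversine(phi, lam, model.origin_lat, model.origin_lon, 1.0)
    return (1.0 - np.cos(d)) / 2.0


# ---------------------------------------------------------------------------
# waveform template
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class WaveformTemplate:
    """Unipolar field-potential shape parameters.

    ``depol_width`` sets the time scale of the complex: the downstroke is a
    Gaussian-shaped dip in dV/dt of width sigma = depol_width / 4 centered
    on the true activation time, and the compensating positive-slope lobes
    sit 3 sigma before/after it, giving an R-to-S peak separation of about
    1.5 depol_width.  ``biphasic balance`` is not a stored field but a
    function of activated-tissue fraction f: balance = 2f - 1 in [-1, +1]
    splits the recovery lobe between before (R wave) and after (QS
    recovery) the downstroke; at f = 0 the deflection is purely negative,
    at f = 1 purely positive, and the peak-to-peak amplitude is the same
    for every morphology.  Because the slope minimum sits at the bottom of
    a smooth, locally symmetric dip, it is not displaced by zero-phase
    low-pass filtering — the property slope-based LAT detection relies on.
    """

    depol_width: float = 2.0e-3        # s
    depol_amplitude: float = 200.0     # uV, peak-to-peak
    fpd_true: float = 0.300            # s
    repol_amplitude: float = 40.0      # uV (signed; >0 = positive T-wave)
    repol_width: float = 0.025         # s (Gaussian sigma of the hump)

    def __post_init__(self):
        if self.depol_width <= 0 or self.depol_amplitude < 0:
            raise ValueError("invalid depolarization parameters")
        if self.fpd_true <= 0 or self.repol_width <= 0:
            raise ValueError("invalid repolarization parameters")

    @property
    def sigma(self) -> float:
        return self.depol_width / 4.0

    @property
    def support(self) -> float:
        """Half-width of the depolarization complex support (s)."""
        return 2.0 * self.depol_width

    @staticmethod
    def balance(activated_frac):
        """Biphasic balance in [-1, 1], monotone in activated fraction."""
        return 2.0 * np.asarray(activated_frac, dtype=float) - 1.0

    def depol_waveform(self, t, balance: float) -> np.ndarray:
        """Depolarization complex; steepest negative slope at t = 0.

        Built from its slope: dV/dt = -D(t) + p R(t + 3 sigma)
        + q R(t - 3 sigma), with D and R Gaussian humps of equal area
        (sigma wide), p = (1+balance)/2 and q = 1 - p.  Integrating gives
        V(t) = A [p Phi((t+3s)/s) - Phi(t/s) + q Phi((t-3s)/s)] with Phi the
        normal CDF: the wave rises by pA, falls by A through the downstroke
        at t = 0, and recovers by qA, so peak-to-peak is A for every
        balance.  The slope minimum is the bottom of the smooth -D dip and
        is therefore stable under (zero-phase) low-pass filtering.
        """
        t = np.asarray(t, dtype=float)
        return self.depol_amplitude * self._shape(t, balance) \
            / self._pkpk(balance)

    def _shape(self, t, balance: float) -> np.ndarray:
        from scipy.special import ndtr
        s = self.sigma
        p = (1.0 + balance) / 2.0
        q = 1.0 - p
        return (p * ndtr((t + 3.0 * s) / s) - ndtr(t / s)
                + q * ndtr((t - 3.0 * s) / s))

    def _pkpk(self, balance: float) -> float:
        """Peak-to-peak of the unscaled shape (lobe overlap makes it a few
        percent below 1); evaluated densely so amplitude is exact."""
        t = np.linspace(-self.support, self.support, 1601)
        return float(np.ptp(self._shape(t, balance)))

    def repol_waveform(self, t) -> np.ndarray:
        """Repolarization hump centered at t = 0 (place at LAT + fpd_true)."""
        t = np.asarray(t, dtype=float)
        return self.repol_amplitude * np.exp(-(t ** 2)
                                             / (2.0 * self.repol_width ** 2))


@dataclass(frozen=True)
class NoiseModel:
    sigma_white: float = 0.0       # uV at the acquisition rate
    line_amplitude: float = 0.0    # uV
    line_freq: float = 60.0        # Hz
    seed: int = 0

    def __post_init__(self):
        if self.sigma_white < 0 or self.line_amplitude < 0:
            raise ValueError("noise amplitudes must be >= 0")


def sigma_for_snr(template: WaveformTemplate, snr: float) -> float:
    """White-noise sigma giving the requested raw-recording SNR
    (peak-to-peak depolarization amplitude / sigma at the acquisition rate)."""
    if snr <= 0:
        raise ValueError("snr must be > 0")
    return template.depol_amplitude / snr


# ---------------------------------------------------------------------------
# electrophysiology simulation
# ---------------------------------------------------------------------------

FIRST_BEAT_OFFSET = 0.25   # s before the first beat anchor


def simulate_recording(layout: ElectrodeLayout, model: WavefrontModel,
                       template: WaveformTemplate, noise: NoiseModel,
                       fs: float = 30000.0, duration: float | None = None,
                       ) -> tuple[MultichannelRecording, pd.DataFrame]:
    """Synthesize a multichannel recording plus its ground-truth table.

    Beats are anchored at ``FIRST_BEAT_OFFSET + k * beat_period``; electrode
    ``e`` activates ``d_e / speed`` after each anchor.  Beats whose
    repolarization would run past ``duration`` are dropped.  The ground-truth
    table has columns (channel, beat, true_lat, true_fpd), ``true_lat`` in
    absolute seconds.
    """
    if fs < 4.0 / template.depol_width:
        raise ValueError("sampling rate too low for the waveform template")
    if duration is None:
        duration = FIRST_BEAT_OFFSET + model.n_beats * model.beat_period
    if duration < model.beat_period:
        raise ValueError("duration shorter than one beat period")

    n = int(round(duration * fs))
    t_end = n / fs
    delays = (haversine(layout.phi, layout.lam, model.origin_lat,
                        model.origin_lon, model.sphere_radius) / model.speed)
    frac = activated_fraction(layout.phi, layout.lam, model)
    balances = WaveformTemplate.balance(frac)

    tail = (delays.max() + template.fpd_true + 4.0 * template.repol_width)
    anchors = [FIRST_BEAT_OFFSET + k * model.beat_period
               for k in range(model.n_beats)
               if FIRST_BEAT_OFFSET + k * model.beat_period + tail <= t_end]
    if not anchors:
        raise ValueError("duration too short to contain one full beat")

    signals = np.zeros((layout.n_electrodes, n))
    truth_rows = []
    half_dep = template.support
    half_rep = 4.0 * template.repol_width
    for ci in range(layout.n_electrodes):
        for bi, a in enumerate(anchors):
            lat = a + delays[ci]
            i0 = max(int(math.floor((lat - half_dep) * fs)), 0)
            i1 = min(int(math.ceil((lat + half_dep) * fs)) + 1, n)
            tt = np.arange(i0, i1) / fs - lat
            signals[ci, i0:i1] += template.depol_waveform(tt, balances[ci])
            rc = lat + template.fpd_true
            j0 = max(int(math.floor((rc - half_rep) * fs)), 0)
            j1 = min(int(math.ceil((rc + half_rep) * fs)) + 1, n)
            signals[ci, j0:j1] += template.repol_waveform(
                np.arange(j0, j1) / fs - rc)
            truth_rows.append((layout.channel_ids[ci], bi, lat,
                               template.fpd_true))

    if noise.sigma_white > 0 or noise.line_amplitude > 0:
        root = np.random.SeedSequence(noise.seed)
        phase_rng = np.random.default_rng(root.spawn(1)[0])
        line_phase = phase_rng.uniform(0, 2 * math.pi)
        if noise.line_amplitude > 0:
            t = np.arange(n) / fs
            signals += noise.line_amplitude * np.sin(
                2 * math.pi * noise.line_freq * t + line_phase)
        if noise.sigma_white > 0:
            streams = root.spawn(1 + layout.n_electrodes)[1:]
            for ci, ss in enumerate(streams):
                signals[ci] += np.random.default_rng(ss).normal(
                    0.0, noise.sigma_white, size=n)

    rec = MultichannelRecording(signals, fs, layout.channel_ids)
    truth = pd.DataFrame(truth_rows,
                         columns=["channel", "beat", "true_lat", "true_fpd"])
    return rec, truth


def apply_drug_effect(model: WavefrontModel, template: WaveformTemplate,
                      rate_factor: float = 1.0, amplitude_factor: float = 1.0,
                      fpd_factor: float = 1.0, speed_factor: float = 1.0,
                      ) -> tuple[WavefrontModel, WaveformTemplate]:
    """Scale beat rate, amplitude, FPD and conduction speed multiplicatively.

    ``rate_factor`` 1.84 on a 48 bpm baseline gives an 84% faster true rate
    (beat_period is divided); all other parameters are untouched.
    """
    for name, f in [("rate_factor", rate_factor),
                    ("amplitude_factor", amplitude_factor),
                    ("fpd_factor", fpd_factor),
                    ("speed_factor", speed_factor)]:
        if not (f > 0):
            raise ValueError(f"{name} must be > 0")
    model2 = replace(model, beat_period=model.beat_period / rate_factor,
                     speed=model.speed * speed_factor)
    template2 = replace(template,
                        depol_amplitude=template.depol_amplitude * amplitude_factor,
                        fpd_true=template.fpd_true * fpd_factor)
    return model2, template2


# ---------------------------------------------------------------------------
# calcium-imaging simulation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CalciumImagingConfig:
    frame_rate: float = 60.0          # Hz
    pixel_size: float = 4.0           # um / pixel
    image_shape: tuple = (160, 160)   # (h, w) pixels
    rise_time: float = 0.04           # s, 10-90% upstroke
    decay_time: float = 0.40          # s, exponential decay constant
    photon_noise_sigma: float = 0.0   # a.u.
    baseline: float = 20.0            # a.u.
    amplitude: float = 100.0          # a.u., plateau above baseline
    occlusion_mask: np.ndarray | None = None   # True = occluded

    def __post_init__(self):
        if self.frame_rate <= 0 or self.pixel_size <= 0:
            raise ValueError("frame_rate and pixel_size must be > 0")
        if self.rise_time <= 0 or self.decay_time <= 0:
            raise ValueError("rise/decay times must be > 0")
        if self.occlusion_mask is not None and \
                tuple(self.occlusion_mask.shape) != tuple(self.image_shape):
            raise ValueError("occlusion_mask shape must equal image_shape")

    @property
    def pixel_size_cm(self) -> float:
        return self.pixel_size * 1e-4


@dataclass
class FrameStack:
    """Fluorescence movie: (t, h, w) intensities in arbitrary units."""

    frames: np.ndarray
    frame_rate: float
    pixel_size: float      # um / pixel

    def __post_init__(self):
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 3 or self.frames.shape[0] < 2:
            raise ValueError("need a (t, h, w) stack with >= 2 frames")
        if self.frame_rate <= 0:
            raise ValueError("frame_rate must be > 0")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def image_shape(self) -> tuple:
        return self.frames.shape[1:]


def render_movie(lat_image: np.ndarray, valid: np.ndarray,
                 cfg: CalciumImagingConfig, duration: float | None = None,
                 seed: int = 0) -> FrameStack:
    """Render a one-beat fluorescence movie from a ground-truth LAT image.

    Each valid pixel follows baseline + amplitude * s(t - LAT) where s is a
    logistic upstroke (10-90% time = rise_time) times an exponential decay;
    half-maximum of the rise is crossed at the pixel's LAT.  Invalid pixels
    stay at baseline.  Gaussian photon noise is added everywhere.
    """
    lat_image = np.asarray(lat_image, dtype=float)
    valid = np.asarray(valid, dtype=bool)
    if duration is None:
        duration = float(np.nanmax(np.where(valid, lat_image, 0.0))) + 0.35
    nf = int(round(duration * cfg.frame_rate))
    if nf < 2:
        raise ValueError("duration too short for two frames")
    tau_r = cfg.rise_time / (2.0 * math.log(9.0))   # logistic 10-90% spread
    t = np.arange(nf) / cfg.frame_rate
    dt = t[:, None, None] - np.where(valid, lat_image, np.inf)[None, :, :]
    with np.errstate(over="ignore", invalid="ignore"):
        upstroke = 1.0 / (1.0 + np.exp(-dt / tau_r))
        decay = np.exp(-np.clip(dt, 0.0, None) / cfg.decay_time)
    frames = cfg.baseline + cfg.amplitude * np.where(
        np.isfinite(dt), upstroke * decay, 0.0)
    if cfg.occlusion_mask is not None:
        frames[:, cfg.occlusion_mask] = cfg.baseline
    if cfg.photon_noise_sigma > 0:
        rng = np.random.default_rng(seed)
        frames = frames + rng.normal(0.0, cfg.photon_noise_sigma,
                                     size=frames.shape)
    return FrameStack(frames, cfg.frame_rate, cfg.pixel_size)


CA_T0 = 0.1   # s of pre-activation baseline in simulated movies


def simulate_calcium_movie(model: WavefrontModel, cfg: CalciumImagingConfig,
                           view: str = "upper", seed: int = 0,
                           ) -> tuple[FrameStack, np.ndarray, np.ndarray]:
    """Simulate one beat of calcium activity seen from above or below.

    The visible hemisphere is orthographically projected onto the image
    plane; each in-organoid pixel's upstroke time is the projected surface
    point's true activation time (offset by ``CA_T0``).  Returns
    (movie, ground-truth LAT image in s, valid mask).  Occluded pixels carry
    baseline + noise only and are excluded from the valid mask.
    """
    phi, lam, inside = orthographic_grid(cfg.image_shape, cfg.pixel_size_cm,
                                         model.sphere_radius, view)
    lat_img = np.full(cfg.image_shape, np.nan)
    lat_img[inside] = (true_activation_time(phi[inside], lam[inside], model)
                       + CA_T0)
    valid = inside.copy()
    if cfg.occlusion_mask is not None:
        valid &= ~cfg.occlusion_mask
    stack = render_movie(np.where(valid, lat_img, 0.0), valid, cfg, seed=seed)
    lat_img[~valid] = np.nan
    return stack, lat_img, valid


def planar_wave_lat_image(image_shape, pixel_size_cm: float, speed: float,
                          angle: float = 0.0, t0: float = CA_T0):
    """Ground-truth LAT image of a planar wave crossing the field of view.

    Upstroke time is linear in the propagation coordinate:
    t = t0 + (x cos(angle) + y sin(angle) - min) / speed, speed in cm/s.
    """
    if speed <= 0:
        raise ValueError("speed must be > 0")
    h, w = image_shape
    Y, X = np.meshgrid(np.arange(h) * pixel_size_cm,
                       np.arange(w) * pixel_size_cm, indexing="ij")
    coord = X * math.cos(angle) + Y * math.sin(angle)
    lat = t0 + (coord - coord.min()) / speed
    return lat, np.ones(image_shape, dtype=bool)
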