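"""Field-potential preprocessing and signal-to-noise estimation.

Raw shell-MEA recordings are acquired at 30 kHz in microvolts.  The standard
preprocessing chain downsamples to 10 kHz (anti-alias filtered), applies a
low-pass (1000 Hz by default, 100 Hz for noisy recordings) and an optional
60 Hz notch to suppress line interference.  All filters run zero-phase
(forward-backward) by default so that activation times are not shifted by
filter group delay.

SNR is the peak-to-peak amplitude over the beat windows divided by the
standard deviation of the signal outside them.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from fractions import Fraction

import numpy as np
from scipy import signal as sps


@dataclass
class MultichannelRecording:
    """Sampled extracellular voltages, one row per electrode (microvolts)."""

    signals: np.ndarray          # (n_channels, n_samples), uV
    fs: float                    # Hz
    channel_ids: tuple
    t0: float = 0.0              # s

    def __post_init__(self):
        self.signals = np.atleast_2d(np.asarray(self.signals, dtype=float))
        self.channel_ids = tuple(self.channel_ids)
        if self.fs <= 0:
            raise ValueError("sampling rate must be > 0")
        if len(self.channel_ids) != self.signals.shape[0]:
            raise ValueError("one channel id per signal row required")
        if len(set(self.channel_ids)) != len(self.channel_ids):
            raise ValueError("channel_ids must be unique")

    @property
    def n_channels(self) -> int:
        return self.signals.shape[0]

    @property
    def n_samples(self) -> int:
        return self.signals.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.fs

    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.n_samples) / self.fs

    def channel(self, channel_id) -> np.ndarray:
        return self.signals[self.channel_ids.index(channel_id)]


@dataclass(frozen=True)
class FilterConfig:
    """Preprocessing settings.

    ``lowpass_hz``: post-decimation low-pass cutoff (1000 Hz default; use
    100 Hz for recordings with strong interference).  ``notch_hz``: line
    filter center, or ``None`` to skip.  ``downsample_to``: output rate.
    """

    lowpass_hz: float = 1000.0
    notch_hz: float | None = 60.0
    downsample_to: float = 10000.0
    zero_phase: bool = True
    order: int = 4
    notch_q: float = 30.0

    def __post_init__(self):
        if self.order < 1:
            raise ValueError("filter order must be >= 1")
        if not self.lowpass_hz < self.downsample_to / 2:
            raise ValueError("low-pass cutoff must be below the output Nyquist")


def _filt(sos, x, zero_phase):
    return sps.sosfiltfilt(sos, x, axis=-1) if zero_phase else sps.sosfilt(sos, x, axis=-1)


def preprocess(rec: MultichannelRecording, cfg: FilterConfig | None = None
               ) -> MultichannelRecording:
    """Decimate, low-pass and notch a recording.

    Integer rate ratios use anti-alias filtering (Butterworth at 0.8x the new
    Nyquist) followed by sample decimation, so a 30 kHz recording of length n
    comes out at 10 kHz with ceil(n/3) samples.  Non-integer ratios fall back
    to polyphase resampling (``scipy.signal.resample_poly``).
    """
    if cfg is None:
        cfg = FilterConfig()
    if rec.fs < cfg.downsample_to:
        raise ValueError("recording rate below the requested output rate")
    x = rec.signals
    ratio = Fraction(rec.fs / cfg.downsample_to).limit_denominator(1000)
    if ratio.denominator == 1 and ratio.numerator > 1:
        q = ratio.numerator
        nyq_new = cfg.downsample_to / 2.0
        sos = sps.butter(8, 0.8 * nyq_new, fs=rec.fs, output="sos")
        x = _filt(sos, x, cfg.zero_phase)[:, ::q]
    elif ratio != 1:
        x = sps.resample_poly(x, ratio.denominator, ratio.numerator, axis=-1)
    fs = cfg.downsample_to

    sos_lp = sps.butter(cfg.order, cfg.lowpass_hz, fs=fs, output="sos")
    x = _filt(sos_lp, x, cfg.zero_phase)
    if cfg.notch_hz is not None:
        b, a = sps.iirnotch(cfg.notch_hz, cfg.notch_q, fs=fs)
        sos_n = sps.tf2sos(b, a)
        x = _filt(sos_n, x, cfg.zero_phase)
    return MultichannelRecording(x, fs, rec.channel_ids, rec.t0)


@dataclass(frozen=True)
class SNRResult:
    amplitude: float      # uV, peak-to-peak over beat windows
    sigma_noise: float    # uV, std of the complement
    snr: float


def compute_snr(x: np.ndarray, beat_windows, min_noise_samples: int = 100
                ) -> SNRResult:
    """Amplitude / noise-sigma for one channel.

    ``beat_windows`` is a list of (start, end) sample intervals (end
    exclusive).  Amplitude is max - min over their union; sigma is the
    standard deviation of everything outside them.
    """
    x = np.asarray(x, dtype=float)
    if len(beat_windows) == 0:
        raise ValueError("at least one beat window required")
    in_beat = np.zeros(x.size, dtype=bool)
    for s, e in beat_windows:
        s = max(int(s), 0)
        e = min(int(e), x.size)
        in_beat[s:e] = True
    if not in_beat.any():
        raise ValueError("beat windows fall outside the signal")
    noise = x[~in_beat]
    if noise.size < min_noise_samples:
        raise ValueError("insufficient noise segment outside beat windows")
    amplitude = float(x[in_beat].max() - x[in_beat].min())
    sigma = float(noise.std())
    if sigma == 0.0:
        raise ValueError("degenerate noise segment: sigma_noise = 0")
    return SNRResult(amplitude, sigma, amplitude / sigma)


def ensemble_average(x: np.ndarray, centers: np.ndarray, fs: float,
                     pre: float, post: float) -> tuple[np.ndarray, np.ndarray]:
    """Average beat-aligned windows of one channel.

    ``centers`` are alignment times in seconds (typically per-beat LATs).
    Returns (t_rel, mean_waveform); windows that would run off either end of
    the signal are dropped.
    """
    x = np.asarray(x, dtype=float)
    n_pre = int(round(pre * fs))
    n_post = int(round(post * fs))
    segs = []
    for c in np.asarray(centers, dtype=float):
        ci = int(round(c * fs))
        if ci - n_pre < 0 or ci + n_post > x.size:
            continue
        segs.append(x[ci - n_pre: ci + n_post])
    if not segs:
        raise ValueError("no complete beat windows to average")
    t_rel = (np.arange(-n_pre, n_post)) / fs
    return t_rel, np.mean(segs, axis=0)


def ensemble_average_realigned(x: np.ndarray, centers: np.ndarray, fs: float,
                               pre: float, post: float,
                               align_half: float = 2e-3
                               ) -> tuple[np.ndarray, np.ndarray]:
    """Beat-ensemble average with template cross-correlation realignment.

    A first-pass average (aligned at ``centers``) serves as template; each
    beat is then shifted by the lag (within ``+/-align_half`` s, parabolically
    refined to sub-sample precision) that maximizes its correlation with the
    template, and the shifted segments are averaged.  Removes the ensemble
    smearing that residual per-beat alignment jitter causes.
    """
    t_rel, template = ensemble_average(x, centers, fs, pre, post)
    n_pre = int(round(pre * fs))
    n_post = int(round(post * fs))
    L = int(round(align_half * fs))
    nseg = n_pre + n_post
    segs = []
    tmpl = template - template.mean()
    for c in np.asarray(centers, dtype=float):
        ci = int(round(c * fs))
        if ci - n_pre - L < 0 or ci + n_post + L > x.size:
            continue
        ext = x[ci - n_pre - L: ci + n_post + L]
        corr = np.correlate(ext - ext.mean(), tmpl, mode="valid")  # 2L+1 lags
        k = int(np.argmax(corr))
        dk = 0.0
        if 1 <= k <= corr.size - 2:
            y0, y1, y2 = corr[k - 1], corr[k], corr[k + 1]
            den = y0 - 2 * y1 + y2
            if den < 0:
                dk = float(np.clip(0.5 * (y0 - y2) / den, -0.5, 0.5))
        shift = (k + dk) - L
        idx = np.arange(nseg) + L + shift
        segs.append(np.interp(idx, np.arange(ext.size), ext))
    if not segs:
        return t_rel, template
    return t_rel, np.mean(segs, axis=0)


def rec_with_signals(rec: MultichannelRecording, signals: np.ndarray
                     ) -> MultichannelRecording:
    return replace(rec, signals=signals)
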