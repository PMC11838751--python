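"""Waveform metrics: field-potential amplitude, beat rate, FPD, drug deltas.

Amplitude is the peak-to-peak voltage of the field potential; beat rate is
60 / mean inter-beat interval (LAT to LAT); FPD is the time from the LAT to
the repolarization peak, taken as the dominant (largest absolute) extremum in
a search window that starts a blanking interval after the LAT and ends before
the next beat.  At realistic noise levels amplitude and FPD are measured on
the beat-ensemble-averaged waveform of each channel (beats aligned at their
LATs), which suppresses the upward bias that per-beat extremes of noisy
traces carry; per-beat values remain available for inspection.

Drug responses are summarized as per-channel percent changes
(post - pre) / pre x 100 with cross-channel mean +/- SEM and a paired t-test
p-value as standard reporting plumbing.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal as sps
from scipy import stats

from .activation import LATTable
from .sigproc import (MultichannelRecording, ensemble_average,
                      ensemble_average_realigned)

__all__ = [
    "beat_rate",
    "fpd",
    "WaveformMetrics",
    "waveform_metrics",
    "DrugResponse",
    "drug_response",
]


def beat_rate(lats) -> float:
    """Beats per minute from the sorted LATs of one channel."""
    lats = np.sort(np.asarray(lats, dtype=float))
    lats = lats[np.isfinite(lats)]
    if lats.size < 2:
        raise ValueError("need >= 2 LATs for a beat rate")
    ibi = np.diff(lats)
    return 60.0 / float(ibi.mean())


def _smooth_for_repol(x: np.ndarray, fs: float, cutoff: float) -> np.ndarray:
    if cutoff is None or cutoff >= fs / 2:
        return x
    sos = sps.butter(4, cutoff, fs=fs, output="sos")
    return sps.sosfiltfilt(sos, x)


def fpd(x: np.ndarray, lat: float, fs: float, blanking: float = 0.05,
        search_end: float | None = None, t0: float = 0.0,
        repol_lowpass_hz: float | None = 30.0) -> float:
    """Field-potential duration of one beat (seconds).

    ``x`` is the beat window, ``t0`` the absolute time of its first sample,
    ``lat`` the absolute LAT.  The repolarization peak is the dominant
    extremum of the (optionally low-passed, median-subtracted) signal
    in (lat + blanking, search_end]; ``search_end`` defaults to the window
    end.  A peak on the search boundary triggers a warning.
    """
    x = np.asarray(x, dtype=float)
    n = x.size
    t_end = t0 + n / fs
    if search_end is None:
        search_end = t_end
    i0 = int(np.ceil((lat + blanking - t0) * fs))
    i1 = min(int(np.floor((search_end - t0) * fs)) + 1, n)
    if i0 >= i1 or i0 < 0:
        raise ValueError("empty FPD search interval")
    seg = _smooth_for_repol(x, fs, repol_lowpass_hz)[i0:i1]
    seg = seg - np.median(seg)
    k = int(np.argmax(np.abs(seg)))
    if k == 0 or k == seg.size - 1:
        import warnings
        warnings.warn("repolarization extremum on search-interval boundary",
                      stacklevel=2)
    return t0 + (i0 + k) / fs - lat


@dataclass
class WaveformMetrics:
    """Per-channel summary of one recording."""

    channel_id: str
    amplitude: float                 # uV, peak-to-peak
    beat_rate: float                 # bpm
    fpd: float                       # s
    interbeat_intervals: np.ndarray  # s
    n_beats: int


def waveform_metrics(rec: MultichannelRecording, table: LATTable,
                     blanking: float = 0.05,
                     repol_lowpass_hz: float | None = 30.0,
                     ensemble: bool = True,
                     amp_halfwindow: float = 0.025) -> list[WaveformMetrics]:
    """Amplitude, beat rate and FPD for every channel.

    With ``ensemble=True`` (default) amplitude and FPD are taken from the
    beat-averaged waveform aligned at the per-beat LATs; the averaging window
    spans from 50 ms before the LAT to 50 ms before the median inter-beat
    interval, so it contains the full depolarization-repolarization complex
    of exactly one beat.  Amplitude is peak-to-peak within
    ``+/-amp_halfwindow`` of the LAT, i.e. over the depolarization spike
    rather than the slow repolarization wave.
    """
    out = []
    for ci, cid in enumerate(rec.channel_ids):
        lats = table.lats[ci]
        lats = np.sort(lats[np.isfinite(lats)])
        if lats.size < 2:
            raise ValueError(f"channel {cid}: not enough beats for metrics")
        ibi = np.diff(lats)
        rate = 60.0 / float(ibi.mean())
        period = float(np.median(ibi))
        pre, post = 0.05, period - 0.05
        if ensemble:
            t_rel, avg = ensemble_average_realigned(
                rec.signals[ci], lats - rec.t0, rec.fs, pre, post)
            spike = avg[np.abs(t_rel) <= amp_halfwindow]
            amplitude = float(np.ptp(spike))
            f = fpd(avg, 0.0, rec.fs, blanking=blanking, t0=float(t_rel[0]),
                    repol_lowpass_hz=repol_lowpass_hz)
        else:
            amps, fpds = [], []
            for lat in lats:
                s = int(round((lat - rec.t0 - pre) * rec.fs))
                e = int(round((lat - rec.t0 + post) * rec.fs))
                if s < 0 or e > rec.n_samples:
                    continue
                seg = rec.signals[ci, s:e]
                tt = rec.t0 + np.arange(s, e) / rec.fs - lat
                amps.append(np.ptp(seg[np.abs(tt) <= amp_halfwindow]))
                fpds.append(fpd(seg, lat, rec.fs, blanking=blanking,
                                t0=rec.t0 + s / rec.fs,
                                repol_lowpass_hz=repol_lowpass_hz))
            amplitude = float(np.median(amps))
            f = float(np.median(fpds))
        out.append(WaveformMetrics(cid, amplitude, rate, f, ibi, lats.size))
    return out


@dataclass
class DrugResponse:
    """Pre/post metrics with percent changes and a cross-channel summary."""

    per_channel: pd.DataFrame        # channel x metric percent changes
    summary: pd.DataFrame            # mean, sem, p_paired per metric
    pre: list
    post: list


_METRICS = ("amplitude", "beat_rate", "fpd")


def drug_response(pre: list[WaveformMetrics], post: list[WaveformMetrics]
                  ) -> DrugResponse:
    """Percent change per channel and metric between two recordings.

    Channels present in only one recording are excluded (and reported via the
    index of ``per_channel``).  percent_change = (post - pre) / pre x 100.
    """
    pre_by = {m.channel_id: m for m in pre}
    post_by = {m.channel_id: m for m in post}
    common = [c for c in pre_by if c in post_by]
    if not common:
        raise ValueError("no channel present in both recordings")
    rows = {}
    for cid in common:
        rows[cid] = {
            name: (getattr(post_by[cid], name) - getattr(pre_by[cid], name))
            / getattr(pre_by[cid], name) * 100.0
            for name in _METRICS
        }
    per_channel = pd.DataFrame.from_dict(rows, orient="index")
    per_channel.index.name = "channel"
    summ = {}
    for name in _METRICS:
        pre_v = np.array([getattr(pre_by[c], name) for c in common])
        post_v = np.array([getattr(post_by[c], name) for c in common])
        pc = per_channel[name].to_numpy()
        sem = float(pc.std(ddof=1) / np.sqrt(pc.size)) if pc.size > 1 else np.nan
        if pc.size > 1 and np.ptp(post_v - pre_v) > 0:
            pval = float(stats.ttest_rel(post_v, pre_v).pvalue)
        else:
            pval = np.nan
        summ[name] = {"mean_percent_change": float(pc.mean()),
                      "sem_percent_change": sem, "p_paired": pval}
    summary = pd.DataFrame.from_dict(summ, orient="index")
    summary.index.name = "metric"
    return DrugResponse(per_channel, summary, pre, post)
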