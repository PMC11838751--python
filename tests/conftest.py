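"""Shared fixtures: synthetic recordings and movies with known ground truth.

Session-scoped fixtures generate moderately sized data once and are reused
across test modules; everything is derived from explicit seeds.
"""

import numpy as np
import pandas as pd
import pytest

from shellmea import (ElectrodeLayout, FilterConfig, NoiseModel,
                      WavefrontModel, WaveformTemplate, build_lat_table,
                      preprocess, simulate_recording)
from shellmea.synth import sigma_for_snr


@pytest.fixture(scope="session")
def layout():
    return ElectrodeLayout.default()


@pytest.fixture(scope="session")
def model():
    return WavefrontModel(n_beats=8)


@pytest.fixture(scope="session")
def template():
    return WaveformTemplate()


def _truth_matrix(truth: pd.DataFrame, channel_ids) -> np.ndarray:
    piv = truth.pivot(index="channel", columns="beat", values="true_lat")
    return piv.loc[list(channel_ids)].to_numpy()


@pytest.fixture(scope="session")
def noiseless_run(layout, model, template):
    """Noiseless 8-beat recording -> (raw, truth, preprocessed, LAT table)."""
    rec, truth = simulate_recording(layout, model, template, NoiseModel(),
                                    fs=30000.0, duration=11.0)
    pre = preprocess(rec, FilterConfig())
    table, windows = build_lat_table(pre)
    return {"rec": rec, "truth": truth, "pre": pre, "table": table,
            "windows": windows,
            "truth_lats": _truth_matrix(truth, pre.channel_ids)}


@pytest.fixture(scope="session")
def noisy_run(layout, model, template):
    """SNR ~10 recording with 60 Hz interference, same wavefront."""
    sigma = sigma_for_snr(template, 10.0)
    rec, truth = simulate_recording(layout, model, template,
                                    NoiseModel(sigma, 5.0, seed=11),
                                    fs=30000.0, duration=11.0)
    pre = preprocess(rec, FilterConfig())
    table, windows = build_lat_table(pre)
    return {"rec": rec, "truth": truth, "pre": pre, "table": table,
            "windows": windows,
            "truth_lats": _truth_matrix(truth, pre.channel_ids)}
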