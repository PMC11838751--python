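"""Synthetic wavefront, recording and calcium-movie generator."""

import math

import numpy as np
import pytest

from shellmea.spheremap import haversine
from shellmea.synth import (CalciumImagingConfig, NoiseModel, WavefrontModel,
                            WaveformTemplate, apply_drug_effect,
                            planar_wave_lat_image, render_movie,
                            sigma_for_snr, simulate_calcium_movie,
                            simulate_recording, true_activation_time)


# ---------------------------------------------------------------------- #
# wavefront ground truth
# ---------------------------------------------------------------------- #

def test_activation_time_zero_at_origin(model):
    assert true_activation_time(model.origin_lat, model.origin_lon,
                                model) == 0.0


def test_activation_time_antipode_is_pi_r_over_v():
    m = WavefrontModel(origin_lat=0.2, origin_lon=1.0, speed=5.0,
                       sphere_radius=0.025)
    t = true_activation_time(-0.2, 1.0 + math.pi, m)
    assert t == pytest.approx(math.pi * 0.025 / 5.0, rel=1e-12)  # ~15.7 ms
    assert t == pytest.approx(m.max_latency)


def test_activation_time_equidistant_points_agree():
    m = WavefrontModel(origin_lat=0.0, origin_lon=0.0)
    # two points 30 deg east/west of the origin along the equator
    t1 = true_activation_time(0.0, math.radians(30), m)
    t2 = true_activation_time(0.0, -math.radians(30), m)
    assert t1 == pytest.approx(t2, rel=1e-12)


def test_activation_time_monotone_in_distance(model):
    rng = np.random.default_rng(2)
    phi = rng.uniform(-1.4, 1.4, 200)
    lam = rng.uniform(0, 2 * math.pi, 200)
    d = haversine(phi, lam, model.origin_lat, model.origin_lon,
                  model.sphere_radius)
    t = true_activation_time(phi, lam, model)
    order = np.argsort(d)
    assert np.all(np.diff(t[order]) >= -1e-15)


def test_later_beats_offset_by_period(model):
    t0 = true_activation_time(0.3, 0.4, model, beat=0)
    t2 = true_activation_time(0.3, 0.4, model, beat=2)
    assert t2 - t0 == pytest.approx(2 * model.beat_period)


def test_activation_time_rejects_nonfinite(model):
    with pytest.raises(ValueError):
        true_activation_time(np.nan, 0.0, model)


# ---------------------------------------------------------------------- #
# waveform template
# ---------------------------------------------------------------------- #

def test_template_morphology_family(template):
    t = np.linspace(-2 * template.depol_width, 2 * template.depol_width, 4001)
    w_origin = template.depol_waveform(t, -1.0)    # activated fraction 0
    assert w_origin.min() < 0
    assert w_origin.max() < 0.02 * abs(w_origin.min())   # purely negative
    w_distal = template.depol_waveform(t, +1.0)
    assert w_distal.max() > 0
    assert abs(w_distal.min()) < 0.02 * w_distal.max()   # purely positive
    for b in (-1.0, -0.4, 0.0, 0.4, 1.0):
        w = template.depol_waveform(t, b)
        assert np.ptp(w) == pytest.approx(template.depol_amplitude, rel=1e-6)
        d = np.gradient(w, t)
        assert abs(t[np.argmin(d)]) < template.sigma / 4   # downstroke at 0


def test_balance_monotone_in_activated_fraction():
    f = np.linspace(0, 1, 11)
    b = WaveformTemplate.balance(f)
    assert b[0] == -1.0 and b[-1] == 1.0
    assert np.all(np.diff(b) > 0)


def test_template_finite_integral(template):
    t = np.linspace(-2 * template.depol_width, 2 * template.depol_width,
                    20001)
    area = np.trapezoid(template.depol_waveform(t, 0.3), t)
    assert np.isfinite(area)


# ---------------------------------------------------------------------- #
# recording simulation
# ---------------------------------------------------------------------- #

def test_recording_determinism(layout, model, template):
    noise = NoiseModel(sigma_white=20.0, line_amplitude=5.0, seed=99)
    r1, t1 = simulate_recording(layout, model, template, noise, 30000.0, 3.0)
    r2, t2 = simulate_recording(layout, model, template, noise, 30000.0, 3.0)
    assert np.array_equal(r1.signals, r2.signals)
    assert t1.equals(t2)
    r3, _ = simulate_recording(layout, model, template,
                               NoiseModel(20.0, 5.0, seed=100), 30000.0, 3.0)
    assert not np.array_equal(r1.signals, r3.signals)


def test_ground_truth_lats_match_analytic_times(layout, noiseless_run, model):
    truth = noiseless_run["truth"]
    for ci, cid in enumerate(layout.channel_ids):
        sub = truth[truth.channel == cid].sort_values("beat")
        expected = (0.25 + sub.beat.to_numpy() * model.beat_period
                    + true_activation_time(layout.phi[ci], layout.lam[ci],
                                           model))
        assert np.allclose(sub.true_lat.to_numpy(), expected, atol=1e-12)


def test_true_lat_spread_bounded_by_max_latency(noiseless_run, model):
    truth = noiseless_run["truth"]
    per_beat = truth.groupby("beat").true_lat
    spread = (per_beat.max() - per_beat.min()).to_numpy()
    assert np.all(spread <= model.max_latency + 1e-12)    # <= pi r / v


def test_origin_electrode_waveform_dominantly_negative(layout, model,
                                                       template,
                                                       noiseless_run):
    """The earliest-activating electrode (closest to the focus) shows a
    mostly negative deflection; the last one a mostly positive deflection."""
    truth = noiseless_run["truth"]
    rec = noiseless_run["rec"]
    beat0 = truth[truth.beat == 0].set_index("channel").true_lat
    first = beat0.idxmin()
    last = beat0.idxmax()
    for cid, sign in [(first, -1), (last, +1)]:
        lat = beat0[cid]
        s = int((lat - 0.005) * rec.fs)
        e = int((lat + 0.005) * rec.fs)
        seg = rec.channel(cid)[s:e]
        assert sign * (abs(seg.max()) - abs(seg.min())) > 0


def test_recording_rejects_short_duration(layout, model, template):
    with pytest.raises(ValueError):
        simulate_recording(layout, model, template, NoiseModel(), 30000.0,
                           0.5 * model.beat_period)


def test_sigma_for_snr_inverse_relation(template):
    assert sigma_for_snr(template, 10.0) == template.depol_amplitude / 10.0
    with pytest.raises(ValueError):
        sigma_for_snr(template, 0.0)


# ---------------------------------------------------------------------- #
# drug effects
# ---------------------------------------------------------------------- #

def test_drug_identity(model, template):
    m2, t2 = apply_drug_effect(model, template)
    assert m2 == model and t2 == template


def test_drug_rate_factor_yields_184_percent_rate():
    model = WavefrontModel(beat_period=2.0)      # 30 bpm baseline
    m2, _ = apply_drug_effect(model, WaveformTemplate(), rate_factor=1.84)
    assert 60.0 / m2.beat_period == pytest.approx(55.2)


def test_drug_fpd_factor_shortens_fpd(model):
    tpl = WaveformTemplate(fpd_true=0.300)
    _, t2 = apply_drug_effect(model, tpl, fpd_factor=0.80)
    assert t2.fpd_true == pytest.approx(0.240)


def test_drug_rejects_nonpositive_factor(model, template):
    with pytest.raises(ValueError):
        apply_drug_effect(model, template, rate_factor=0.0)


# ---------------------------------------------------------------------- #
# calcium movies
# ---------------------------------------------------------------------- #

def _small_cfg(**kw):
    return CalciumImagingConfig(image_shape=(64, 64), pixel_size=10.0, **kw)


def test_uniform_wavefront_all_upstrokes_equal():
    """In the infinite-speed limit every pixel activates simultaneously."""
    m = WavefrontModel(speed=math.inf)
    stack, lat_img, valid = simulate_calcium_movie(m, _small_cfg())
    assert np.nanmax(lat_img) - np.nanmin(lat_img) == pytest.approx(0.0)


def test_planar_wave_lat_linear_in_propagation_coordinate():
    lat, valid = planar_wave_lat_image((32, 32), 10e-4, speed=2.5)
    # columns advance linearly at 1 / speed per cm
    col_slope = np.diff(lat[0]) / 10e-4
    assert np.allclose(col_slope, 1 / 2.5)
    assert np.allclose(lat[:, 5], lat[0, 5])     # no dependence on y
    assert valid.all()


def test_occluded_pixels_stay_at_baseline():
    occ = np.zeros((64, 64), dtype=bool)
    occ[10:20, 10:20] = True
    cfg = _small_cfg(occlusion_mask=occ, photon_noise_sigma=0.0)
    stack, lat_img, valid = simulate_calcium_movie(WavefrontModel(), cfg)
    assert not valid[12, 12]
    assert np.all(stack.frames[:, 12, 12] == cfg.baseline)
    assert np.isnan(lat_img[12, 12])


def test_movie_determinism():
    cfg = _small_cfg(photon_noise_sigma=3.0)
    s1, *_ = simulate_calcium_movie(WavefrontModel(), cfg, seed=5)
    s2, *_ = simulate_calcium_movie(WavefrontModel(), cfg, seed=5)
    assert np.array_equal(s1.frames, s2.frames)


def test_movie_too_small_image_rejected():
    cfg = CalciumImagingConfig(image_shape=(16, 16), pixel_size=4.0)
    with pytest.raises(ValueError):
        simulate_calcium_movie(WavefrontModel(), cfg)


def test_render_half_max_crossing_at_upstroke_time():
    """The rendered fluorescence crosses half-max at the prescribed LAT to
    within a fraction of the rise time."""
    cfg = CalciumImagingConfig(image_shape=(4, 4), pixel_size=200.0,
                               frame_rate=600.0)   # fine time sampling
    lat = np.full((4, 4), 0.2)
    stack = render_movie(lat, np.ones((4, 4), bool), cfg, duration=0.8)
    tr = stack.frames[:, 0, 0]
    half = tr.min() + 0.5 * (tr.max() - tr.min())
    t_cross = np.argmax(tr >= half) / cfg.frame_rate
    assert abs(t_cross - 0.2) < cfg.rise_time / 2
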