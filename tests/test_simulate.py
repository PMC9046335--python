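"""Synthetic session generators: structure, ground truth, reproducibility."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from gazephys.simulate import (
    CardiacParams,
    ConfigError,
    PupilParams,
    SCParams,
    SimConfig,
    bateman_peak,
    generate_affective_session,
    generate_fixation_saccade_session,
    generate_nn_series,
    generate_plr_session,
    generate_sc_trace,
    grid_targets_px,
    render_pulse_waveform,
)


def test_config_validation():
    with pytest.raises(ConfigError):
        SimConfig(seed=0, loss_prob=1.0)
    with pytest.raises(ConfigError):
        SimConfig(seed=0, rate_hz=0)
    with pytest.raises(ConfigError):
        SimConfig(seed=0, pupil=PupilParams(dark_mm=12.0))
    with pytest.raises(ConfigError):
        SimConfig(seed=0, cardiac=CardiacParams(lf_freq_hz=0.3))
    with pytest.raises(ConfigError):
        SimConfig(seed=0, sc=SCParams(scr_amplitude_us=-1.0))


def test_same_seed_bit_identical():
    a = generate_fixation_saccade_session(SimConfig(seed=7), visits_per_peripheral=1)
    b = generate_fixation_saccade_session(SimConfig(seed=7), visits_per_peripheral=1)
    pd.testing.assert_frame_equal(a[0].samples, b[0].samples)
    pd.testing.assert_frame_equal(a[1], b[1])
    pd.testing.assert_frame_equal(a[2].saccades, b[2].saccades)


def test_grid_spacing(geometry):
    from gazephys.geometry import distance_deg

    pts = grid_targets_px(geometry)
    center = pts[4]
    dists = [distance_deg(tuple(center), tuple(p), geometry) for i, p in enumerate(pts) if i != 4]
    # 4 edge dots one step away, 4 corner dots sqrt(2) steps away
    assert sorted(round(d, 2) for d in dists) == [11.0] * 4 + [round(11 * np.sqrt(2), 2)] * 4


def test_noiseless_fixation_samples_sit_on_target():
    cfg = SimConfig(seed=3, precision_sd_deg=0.0, accuracy_offset_deg=(0.0, 0.0), loss_prob=0.0)
    rec, trials, truth = generate_fixation_saccade_session(cfg, visits_per_peripheral=1)
    t = rec.t
    for tr in trials.itertuples():
        # samples well inside the fixation period (after latency + saccade)
        mask = (t >= tr.onset + 0.5) & (t < tr.offset)
        assert np.allclose(rec.xy[mask, 0], tr.target_x_px)
        assert np.allclose(rec.xy[mask, 1], tr.target_y_px)


def test_peripherals_exhausted_before_repeats():
    _, trials, _ = generate_fixation_saccade_session(SimConfig(seed=5))
    periph = trials[trials.location == "peripheral"]
    keys = list(zip(periph.target_x_px, periph.target_y_px))
    first_round, second_round = keys[:8], keys[8:]
    assert len(set(first_round)) == 8
    assert len(set(second_round)) == 8
    assert len(keys) == 16


def test_central_holds_within_2_to_5_s():
    _, trials, _ = generate_fixation_saccade_session(SimConfig(seed=11))
    central = trials[trials.location == "central"]
    holds = central.offset - central.onset
    assert ((holds >= 2.0) & (holds <= 5.0)).all()


def test_injected_loss_within_binomial_ci():
    cfg = SimConfig(seed=21, loss_prob=0.1)
    rec, _, truth = generate_fixation_saccade_session(cfg)
    n = len(rec)
    frac = len(truth.loss_indices) / n
    ci = 2.58 * np.sqrt(0.1 * 0.9 / n)
    assert abs(frac - 0.1) < ci


def test_main_sequence_truth_durations():
    cfg = SimConfig(seed=2)
    _, _, truth = generate_fixation_saccade_session(cfg, visits_per_peripheral=1)
    s = truth.saccades
    assert np.allclose(s.duration_ms, 2.2 * s.amplitude_deg + 21.0)
    # an 11-degree saccade lasts 45.2 ms under the default law
    edge = s[np.isclose(s.amplitude_deg, 11.0)]
    assert np.allclose(edge.duration_ms, 45.2)


def test_plr_square_wave_limit():
    cfg = SimConfig(
        seed=1,
        pupil=PupilParams(tau_s=0.0, latency_s=0.0, noise_sd_mm=0.0, blink_rate_per_min=0.0),
    )
    rec, stim, truth = generate_plr_session(cfg)
    p = rec.pupil_mm
    t = rec.t
    for e in stim.itertuples():
        mask = (t >= e.onset) & (t < e.offset)
        expected = 6.0 if e.luminance == "black" else 4.0
        assert np.allclose(p[mask], expected)


def test_plr_epoch_structure_and_asymptotes():
    rec, stim, truth = generate_plr_session(SimConfig(seed=4))
    assert len(stim) == 24
    assert (stim.luminance.value_counts() == 12).all()
    assert np.allclose(stim.offset - stim.onset, 5.0)
    t, p = rec.t, rec.pupil_mm
    # steady-state means approach the equilibria
    for e in stim.iloc[2:].itertuples():
        mask = (t >= e.onset + 3.0) & (t < e.offset)
        vals = p[mask]
        vals = vals[np.isfinite(vals)]
        expected = 6.0 if e.luminance == "black" else 4.0
        assert abs(np.mean(vals) - expected) < 0.1


def test_plr_blink_gaps_bounded():
    rec, stim, truth = generate_plr_session(SimConfig(seed=8))
    if len(truth.blink_intervals):
        assert (truth.blink_intervals.duration_ms <= 150.0).all()


def test_affective_session_recovers_coefficients_by_ols():
    cfg = SimConfig(seed=13)
    rec, stim, truth = generate_affective_session(cfg, n_stimuli=50)
    assert np.allclose(stim.stim_offset - stim.stim_onset, 6.0)
    fix = stim.stim_onset - stim.fix_onset
    assert ((fix >= 7.0) & (fix <= 15.0)).all()
    X = np.column_stack([np.ones(len(stim)), stim.arousal, stim.brightness])
    beta, *_ = np.linalg.lstsq(X, stim.true_level_mm, rcond=None)
    assert beta[1] == pytest.approx(truth.affect_coefs["arousal_coef"], abs=0.005)
    assert beta[2] == pytest.approx(-truth.affect_coefs["brightness_coef"], abs=0.1)


def test_nn_series_constant_when_deterministic():
    cfg = SimConfig(
        seed=1, cardiac=CardiacParams(lf_amp_ms=0.0, hf_amp_ms=0.0, noise_sd_ms=0.0)
    )
    nn, truth = generate_nn_series(cfg, 60.0)
    assert np.allclose(nn.rr_ms, 900.0)
    assert truth.sdnn_ms == pytest.approx(0.0)


def test_nn_series_white_noise_sdnn():
    cfg = SimConfig(
        seed=3, cardiac=CardiacParams(lf_amp_ms=0.0, hf_amp_ms=0.0, noise_sd_ms=10.0)
    )
    nn, truth = generate_nn_series(cfg, 600.0)
    assert truth.sdnn_ms == pytest.approx(10.0, rel=0.10)


def test_pulse_waveform_peaks_at_beat_times():
    beats = np.arange(10) * 1.0
    from gazephys.containers import NNSeries

    trace = render_pulse_waveform(NNSeries(beat_times=beats), 150.0)
    # the sample nearest each beat should be a local max within one period
    for b in beats:
        i = np.argmin(np.abs(trace.t - b))
        window = trace.value[max(i - 2, 0) : i + 3]
        assert trace.value[i] == pytest.approx(window.max())
    # amplitude scaling leaves peak locations unchanged
    tr2 = render_pulse_waveform(NNSeries(beat_times=beats), 150.0, amplitude=3.0)
    assert np.array_equal(np.argsort(trace.value)[-5:], np.argsort(tr2.value)[-5:])


def test_pulse_waveform_errors():
    from gazephys.containers import NNSeries

    with pytest.raises(Exception):
        render_pulse_waveform(NNSeries(beat_times=np.array([])), 150.0)
    with pytest.raises(ConfigError):
        render_pulse_waveform(NNSeries(beat_times=np.array([0.0, 0.5, 1.0])), 3.0)


def test_sc_trace_tonic_ramp_and_bateman_peak():
    cfg = SimConfig(seed=2, sc=SCParams(noise_sd_us=0.0))
    trace, truth = generate_sc_trace(cfg, [], duration_s=30.0)
    # pure linear ramp
    fit = stats.linregress(trace.t, trace.value)
    assert fit.slope == pytest.approx(0.005, rel=1e-6)
    assert fit.rvalue == pytest.approx(1.0)

    trace2, truth2 = generate_sc_trace(cfg, [5.0], duration_s=30.0)
    resp = trace2.value - trace.value[: len(trace2.value)]
    t_star, h = bateman_peak(0.75, 2.0)
    i_peak = np.argmax(resp)
    assert trace2.t[i_peak] - 5.0 == pytest.approx(t_star, abs=0.02)
    assert resp[i_peak] == pytest.approx(0.5 * h, rel=1e-3)


def test_sc_event_amplitude_linearity():
    cfg1 = SimConfig(seed=2, sc=SCParams(noise_sd_us=0.0, scr_amplitude_us=0.5))
    cfg2 = SimConfig(seed=2, sc=SCParams(noise_sd_us=0.0, scr_amplitude_us=1.0))
    t1, _ = generate_sc_trace(cfg1, [5.0], duration_s=30.0)
    t2, _ = generate_sc_trace(cfg2, [5.0], duration_s=30.0)
    base, _ = generate_sc_trace(
        SimConfig(seed=2, sc=SCParams(noise_sd_us=0.0)), [], duration_s=30.0
    )
    assert np.allclose(t2.value - base.value, 2.0 * (t1.value - base.value))
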