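"""Pupil cleaning, gap interpolation, baseline correction, PLR, arousal model."""

import numpy as np
import pandas as pd
import pytest

from gazephys.pupil import (
    arousal_model,
    baseline_correct,
    clean_range,
    interpolate_gaps,
    plr_summary,
    stimulus_locked_means,
)
from gazephys.simulate import (
    PupilParams,
    SimConfig,
    generate_affective_session,
    generate_plr_session,
)


def trace_of(values, rate=150.0):
    v = np.asarray(values, float)
    return pd.DataFrame({"t": np.arange(len(v)) / rate, "pupil_mm": v})


def test_clean_range_flags_out_of_range():
    tr = clean_range(trace_of([1.9, 5.0, 10.1, 0.0, 4.0]))
    assert tr.attrs["n_removed"] == 3
    assert np.isnan(tr.pupil_mm[0]) and np.isnan(tr.pupil_mm[2]) and np.isnan(tr.pupil_mm[3])
    assert tr.pupil_mm[1] == 5.0
    untouched = clean_range(trace_of([4.0, 5.0]))
    assert untouched.attrs["n_removed"] == 0


def test_interpolate_short_gap_linear_ramp():
    v = np.full(50, 4.0)
    v[30:] = 5.0
    v[20:30] = np.nan  # 10 samples ~ 67 ms between flanks at 4 and 5 mm
    tr = interpolate_gaps(trace_of(v))
    filled = tr.pupil_mm.to_numpy()
    assert np.all(np.isfinite(filled))
    seg = filled[19:31]
    assert np.all(np.diff(seg) > 0)  # monotone ramp
    assert filled[20] == pytest.approx(np.interp(tr.t[20], [tr.t[19], tr.t[30]], [4, 5]))


def test_interpolate_leaves_long_gaps_and_edges():
    v = np.full(100, 4.0)
    v[40:75] = np.nan  # ~233 ms > 150 ms limit
    v[:5] = np.nan  # edge gap
    tr = interpolate_gaps(trace_of(v))
    assert np.isnan(tr.pupil_mm[50])
    assert np.isnan(tr.pupil_mm[0])
    ident = interpolate_gaps(trace_of(np.full(20, 4.0)))
    assert np.allclose(ident.pupil_mm, 4.0)


def test_interpolation_never_leaves_plausible_band():
    rng = np.random.default_rng(3)
    v = rng.uniform(2.5, 9.5, 200)
    v[50:55] = np.nan
    out = interpolate_gaps(clean_range(trace_of(v)))
    filled = out.pupil_mm.to_numpy()
    assert np.nanmin(filled) >= 2.0 and np.nanmax(filled) <= 10.0


def test_baseline_correction_constant_trace_and_offset_invariance():
    v = np.full(600, 5.0)
    onsets = np.array([0.0, 1.0, 2.0, 3.0])
    out = baseline_correct(trace_of(v), onsets)
    assert np.allclose(out.corrected_mm, 0.0)
    # adding a constant to the whole trace leaves the corrected trace unchanged
    rng = np.random.default_rng(1)
    v2 = 5.0 + 0.2 * np.sin(np.arange(600) / 30.0) + rng.normal(0, 0.02, 600)
    a = baseline_correct(trace_of(v2), onsets)
    b = baseline_correct(trace_of(v2 + 1.3), onsets)
    assert np.allclose(a.corrected_mm, b.corrected_mm)


def test_baseline_window_median_arithmetic():
    # last 20 samples of trial 0 at 4.8 mm, first 20 of trial 1 at 4.8, then 5.0
    v = np.concatenate([np.full(150, 4.8), np.full(20, 4.8), np.full(130, 5.0)])
    onsets = np.array([0.0, 1.0])
    out = baseline_correct(trace_of(v), onsets)
    late = out[(out.trial == 1) & (out.t > 1.5)]
    assert np.allclose(late.corrected_mm, 0.2)
    assert (out[out.trial == 0].baseline_flag == "first_trial").all()


def test_plr_sign_gap_recovery_and_variance():
    cfg = SimConfig(seed=5)
    rec, stim, truth = generate_plr_session(cfg)
    tr = interpolate_gaps(clean_range(rec.samples[["t", "pupil_mm"]].copy()))
    cor = baseline_correct(tr, stim["onset"].to_numpy())
    s = plr_summary(cor, stim)
    gap = truth.pupil_equilibria_mm[0] - truth.pupil_equilibria_mm[1]
    assert s["white_minus_black_mm"] < 0  # constriction to light
    assert s["constriction_amplitude_mm"] == pytest.approx(gap, rel=0.10)
    assert s["variance_explained"] > 0.9


def test_plr_square_wave_variance_explained_one():
    cfg = SimConfig(
        seed=1,
        pupil=PupilParams(tau_s=0.0, latency_s=0.0, noise_sd_mm=0.0, blink_rate_per_min=0.0),
    )
    rec, stim, _ = generate_plr_session(cfg)
    cor = baseline_correct(rec.samples[["t", "pupil_mm"]].copy(), stim["onset"].to_numpy())
    s = plr_summary(cor, stim)
    assert s["variance_explained"] == pytest.approx(1.0, abs=1e-9)


def test_plr_requires_both_luminances():
    cfg = SimConfig(seed=1)
    rec, stim, _ = generate_plr_session(cfg)
    cor = baseline_correct(rec.samples[["t", "pupil_mm"]].copy(), stim["onset"].to_numpy())
    with pytest.raises(ValueError):
        plr_summary(cor, stim[stim.luminance == "black"])


def test_arousal_model_recovers_generator_coefficients():
    cfg = SimConfig(seed=13)
    rec, stim, truth = generate_affective_session(cfg, n_stimuli=50)
    means = stimulus_locked_means(rec.samples[["t", "pupil_mm"]], stim)
    fit = arousal_model(means.corrected_mean_mm, stim.arousal, stim.brightness)
    assert abs(fit.coef_arousal - truth.affect_coefs["arousal_coef"]) < 2 * fit.se_arousal
    assert (
        abs(fit.coef_brightness - (-truth.affect_coefs["brightness_coef"]))
        < 2 * fit.se_brightness
    )
    assert fit.coef_arousal > 0 and fit.coef_brightness < 0


def test_arousal_model_null_coefficient_and_scaling_identity():
    from gazephys.simulate import AffectParams

    cfg = SimConfig(seed=17, affect=AffectParams(arousal_coef=0.0))
    rec, stim, _ = generate_affective_session(cfg, n_stimuli=50)
    means = stimulus_locked_means(rec.samples[["t", "pupil_mm"]], stim)
    fit = arousal_model(means.corrected_mean_mm, stim.arousal, stim.brightness)
    assert abs(fit.coef_arousal) < 2 * fit.se_arousal

    # doubling the brightness scale halves its raw coefficient but not the
    # standardized one
    fit2 = arousal_model(means.corrected_mean_mm, stim.arousal, 2.0 * stim.brightness)
    assert fit2.coef_brightness == pytest.approx(fit.coef_brightness / 2.0)
    assert fit2.coef_brightness_std == pytest.approx(fit.coef_brightness_std)


def test_arousal_model_rejects_collinear_predictors():
    x = np.arange(10, dtype=float)
    with pytest.raises(ValueError):
        arousal_model(np.random.default_rng(0).normal(size=10), x, 2 * x + 1)
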