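"""Pupil-trace cleaning, baseline correction, PLR and arousal/brightness models.

Cleaning follows the usual pupillometry pipeline: physiologically
implausible diameters (outside 2–10 mm) are flagged missing, short gaps
(blinks, up to 150 ms) are linearly interpolated, and a subtractive
baseline correction is applied per trial. The baseline for a trial is the
median diameter over the last 20 samples of the preceding trial plus the
first 20 samples of the trial itself — a window spanning the luminance
change in an alternating design, so the correction is relative to the
preceding steady state.

The pupillary light reflex (PLR) is summarised from per-epoch means of the
corrected trace; arousal/brightness modulation is estimated with ordinary
least squares on mean-centered (optionally standardized) predictors.
"""

from __future__ import annotations

from dataclasses import dataclass
import numpy as np
import pandas as pd
import statsmodels.api as sm

__all__ = [
    "clean_range",
    "interpolate_gaps",
    "baseline_correct",
    "plr_summary",
    "stimulus_locked_means",
    "arousal_model",
    "PupilModelFit",
]


def clean_range(
    trace: pd.DataFrame, lo_mm: float = 2.0, hi_mm: float = 10.0, column: str = "pupil_mm"
) -> pd.DataFrame:
    """Flag diameters outside [lo, hi] mm as missing (NaN).

    Returns a copy with the out-of-range samples set to NaN and an
    ``n_removed`` attribute in ``DataFrame.attrs``.
    """
    out = trace.copy()
    p = out[column].to_numpy(float)
    bad = np.isfinite(p) & ((p < lo_mm) | (p > hi_mm))
    p = p.copy()
    p[bad] = np.nan
    out[column] = p
    out.attrs["n_removed"] = int(bad.sum())
    return out


def interpolate_gaps(
    trace: pd.DataFrame, max_gap_ms: float = 150.0, column: str = "pupil_mm"
) -> pd.DataFrame:
    """Linearly interpolate missing runs no longer than ``max_gap_ms``.

    Gap duration is measured between the flanking valid samples; gaps at
    either edge of the trace are never extrapolated. Longer gaps are left
    missing.
    """
    out = trace.copy()
    t = out["t"].to_numpy(float)
    p = out[column].to_numpy(float).copy()
    isna = ~np.isfinite(p)
    if not isna.any():
        return out
    n = len(p)
    i = 0
    while i < n:
        if isna[i]:
            j = i
            while j + 1 < n and isna[j + 1]:
                j += 1
            left, right = i - 1, j + 1
            if left >= 0 and right < n:
                gap_ms = (t[right] - t[left]) * 1000.0
                if gap_ms <= max_gap_ms:
                    p[i : j + 1] = np.interp(t[i : j + 1], [t[left], t[right]],
                                             [p[left], p[right]])
            i = j + 1
        else:
            i += 1
    out[column] = p
    return out


def baseline_correct(
    trace: pd.DataFrame,
    trial_onsets: np.ndarray,
    n_pre: int = 20,
    n_post: int = 20,
    column: str = "pupil_mm",
) -> pd.DataFrame:
    """Subtractive per-trial baseline correction.

    Trials are the half-open intervals between consecutive onsets (the last
    runs to the end of the trace). The baseline is the median over the last
    ``n_pre`` samples before the trial onset and the first ``n_post``
    samples after it; the first trial, having no predecessor, uses only its
    own first ``n_post`` samples and is flagged. A trial whose window is
    fully missing is flagged uncorrectable (corrected values NaN).

    Returns a copy with columns ``trial``, ``corrected_mm``,
    ``baseline_mm``, ``baseline_flag`` ∈ {ok, first_trial, uncorrectable}.
    """
    onsets = np.asarray(trial_onsets, float)
    out = trace.copy()
    t = out["t"].to_numpy(float)
    p = out[column].to_numpy(float)
    trial = np.clip(np.searchsorted(onsets, t, side="right") - 1, 0, len(onsets) - 1)
    corrected = np.full(len(p), np.nan)
    baselines = np.full(len(onsets), np.nan)
    flags = []
    for k in range(len(onsets)):
        start_idx = int(np.searchsorted(t, onsets[k], side="left"))
        if k == 0:
            window = p[start_idx : start_idx + n_post]
            flag = "first_trial"
        else:
            window = np.concatenate(
                [p[max(start_idx - n_pre, 0) : start_idx], p[start_idx : start_idx + n_post]]
            )
            flag = "ok"
        window = window[np.isfinite(window)]
        mask = trial == k
        if len(window) == 0:
            flags.append("uncorrectable")
            continue
        baselines[k] = np.median(window)
        corrected[mask] = p[mask] - baselines[k]
        flags.append(flag)
    out["trial"] = trial
    out["corrected_mm"] = corrected
    out["baseline_mm"] = baselines[trial]
    out["baseline_flag"] = np.asarray(flags, object)[trial]
    return out


def plr_summary(
    corrected: pd.DataFrame,
    stim: pd.DataFrame,
    steady_after_s: float = 2.0,
    drop_first_epoch: bool = True,
) -> dict:
    """Pupillary-light-reflex effect from a baseline-corrected trace.

    Per epoch, the mean corrected pupil over its steady-state window
    (``steady_after_s`` after epoch onset to epoch offset) is computed.
    With alternating luminance and the rolling baseline, dark epochs sit at
    ≈ +gap and light epochs at ≈ −gap relative to their preceding baseline,
    so the reported ``constriction_amplitude_mm`` — (dark − light)/2 of the
    per-condition means — estimates the equilibrium gap. Variance explained
    is the R² of a two-level fixed-effects (OLS on the luminance indicator)
    fit over epoch means. The first epoch, whose baseline is degenerate, is
    dropped by default.
    """
    lums = stim["luminance"].unique()
    if len(lums) < 2:
        raise ValueError("PLR summary needs epochs of both luminances")
    t = corrected["t"].to_numpy(float)
    c = corrected["corrected_mm"].to_numpy(float)
    rows = []
    it = stim.iloc[1:] if drop_first_epoch else stim
    for e in it.itertuples():
        mask = (t >= e.onset + steady_after_s) & (t < e.offset)
        vals = c[mask]
        vals = vals[np.isfinite(vals)]
        if len(vals):
            rows.append(dict(epoch_id=e.epoch_id, luminance=e.luminance,
                             mean_corrected_mm=float(np.mean(vals))))
    ep = pd.DataFrame(rows)
    means = ep.groupby("luminance")["mean_corrected_mm"].mean()
    black, white = float(means["black"]), float(means["white"])
    y = ep["mean_corrected_mm"].to_numpy(float)
    x = (ep["luminance"] == "white").to_numpy(float)
    fit = sm.OLS(y, sm.add_constant(x)).fit()
    return dict(
        mean_corrected_black_mm=black,
        mean_corrected_white_mm=white,
        white_minus_black_mm=white - black,
        constriction_amplitude_mm=(black - white) / 2.0,
        variance_explained=float(fit.rsquared),
        n_epochs=len(ep),
    )


def stimulus_locked_means(
    trace: pd.DataFrame,
    stim: pd.DataFrame,
    baseline_s: float = 1.0,
    column: str = "pupil_mm",
) -> pd.DataFrame:
    """Baseline-corrected mean pupil per stimulus presentation.

    For each stimulus row (stim_onset, stim_offset) the mean diameter in
    the ``baseline_s`` window before onset is subtracted from the mean
    during the presentation.
    """
    t = trace["t"].to_numpy(float)
    p = trace[column].to_numpy(float)
    rows = []
    for s in stim.itertuples():
        base = p[(t >= s.stim_onset - baseline_s) & (t < s.stim_onset)]
        during = p[(t >= s.stim_onset) & (t < s.stim_offset)]
        base = base[np.isfinite(base)]
        during = during[np.isfinite(during)]
        rows.append(
            dict(
                trial_id=s.trial_id,
                corrected_mean_mm=float(np.mean(during) - np.mean(base))
                if len(base) and len(during)
                else np.nan,
            )
        )
    return pd.DataFrame(rows)


@dataclass
class PupilModelFit:
    """OLS fit of stimulus-locked pupil on arousal and brightness.

    Raw coefficients are per predictor unit; standardized coefficients are
    per predictor SD (predictors mean-centered and scaled before fitting).
    """

    coef_arousal: float
    coef_brightness: float
    se_arousal: float
    se_brightness: float
    coef_arousal_std: float
    coef_brightness_std: float
    intercept: float
    r_squared: float
    n: int


def arousal_model(
    pupil_means: np.ndarray, arousal: np.ndarray, brightness: np.ndarray
) -> PupilModelFit:
    """Regress stimulus-locked pupil means on arousal and brightness.

    Predictors are mean-centered; standardized coefficients additionally
    divide by the predictor SD. Expected signs on a light-reflex +
    arousal-dilation system: arousal positive, brightness negative.
    Raises on collinear predictors.
    """
    y = np.asarray(pupil_means, float)
    a = np.asarray(arousal, float)
    b = np.asarray(brightness, float)
    keep = np.isfinite(y) & np.isfinite(a) & np.isfinite(b)
    y, a, b = y[keep], a[keep], b[keep]
    if len(y) < 3:
        raise ValueError("need at least 3 stimuli for the arousal model")
    ac, bc = a - a.mean(), b - b.mean()
    X = sm.add_constant(np.column_stack([ac, bc]))
    if np.linalg.matrix_rank(X) < 3:
        raise ValueError("collinear predictors: arousal and brightness")
    fit = sm.OLS(y, X).fit()
    sa, sb = np.std(a, ddof=1), np.std(b, ddof=1)
    return PupilModelFit(
        coef_arousal=float(fit.params[1]),
        coef_brightness=float(fit.params[2]),
        se_arousal=float(fit.bse[1]),
        se_brightness=float(fit.bse[2]),
        coef_arousal_std=float(fit.params[1] * sa),
        coef_brightness_std=float(fit.params[2] * sb),
        intercept=float(fit.params[0]),
        r_squared=float(fit.rsquared),
        n=len(y),
    )
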