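"""Synthetic gaze, pupil, pulse, and skin-conductance sessions with ground truth.

The generators emulate the structure of three screen tasks commonly used to
validate a remote eye-tracker plus a finger-worn biometrics unit:

* a fixation–saccade task: a 3×3 dot grid where a target jumps between the
  central dot and randomly chosen peripheral dots (central holds 2–5 s,
  every peripheral exhausted before any repeats);
* a pupillary light reflex (PLR) task: full-screen black/white backgrounds
  alternating every 5 s, 12 presentations of each;
* an affective picture task: a 7–15 s fixation followed by a 6 s image with
  known arousal and brightness covariates driving the pupil.

On the physiological side the module produces inter-beat-interval (IBI)
series with controlled LF/HF sinusoidal modulation, a smooth PPG-like pulse
waveform rendered from beat times, and skin-conductance traces with a tonic
drift plus bi-exponential (Bateman) phasic responses.

Every generator returns a :class:`GroundTruth` record holding the true
parameters and event times, so each downstream analysis can be tested by
parameter recovery. Identical ``SimConfig`` (including the seed) yields
bit-identical output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .containers import GazeRecording, NNSeries, PhysioTrace
from .geometry import ScreenGeometry, distance_deg

__all__ = [
    "SimConfig",
    "GroundTruth",
    "ConfigError",
    "DEFAULT_SCREEN",
    "generate_fixation_saccade_session",
    "generate_plr_session",
    "generate_affective_session",
    "generate_nn_series",
    "render_pulse_waveform",
    "generate_sc_trace",
    "bateman",
    "bateman_peak",
]

#: Typical desktop validation setup: 53 × 30 cm, 1920 × 1080 px, viewed at 62.45 cm.
DEFAULT_SCREEN = ScreenGeometry(
    width_cm=53.0, height_cm=30.0, width_px=1920, height_px=1080, distance_cm=62.45
)


class ConfigError(ValueError):
    """Invalid simulation configuration."""


@dataclass(frozen=True)
class MainSequenceParams:
    """Linear amplitude→duration law: duration_ms = slope·amplitude_deg + intercept."""

    slope_ms_per_deg: float = 2.2
    intercept_ms: float = 21.0


@dataclass(frozen=True)
class PupilParams:
    """First-order pupillary light response parameters.

    The pupil approaches a luminance-dependent equilibrium exponentially
    with time constant ``tau_s`` after a constriction/dilation latency.
    Equilibria must lie in the physiologically plausible 2–10 mm band.
    """

    dark_mm: float = 6.0
    light_mm: float = 4.0
    tau_s: float = 0.4
    latency_s: float = 0.2
    noise_sd_mm: float = 0.05
    blink_rate_per_min: float = 4.0
    blink_duration_ms: float = 100.0


@dataclass(frozen=True)
class AffectParams:
    """Stimulus-locked pupil model: baseline + β_a·arousal − β_b·brightness + ε."""

    baseline_mm: float = 4.5
    arousal_coef: float = 0.02  # mm per rating unit (ratings on −10..+10)
    brightness_coef: float = 0.5  # mm per unit brightness (brightness in 0..1)
    noise_sd_mm: float = 0.05


@dataclass(frozen=True)
class CardiacParams:
    """IBI model: mean + LF and HF sinusoids + white noise, optional artifacts."""

    mean_ibi_ms: float = 900.0
    lf_freq_hz: float = 0.1
    lf_amp_ms: float = 30.0
    hf_freq_hz: float = 0.25
    hf_amp_ms: float = 20.0
    noise_sd_ms: float = 10.0
    artifact_rate: float = 0.0


@dataclass(frozen=True)
class SCParams:
    """Skin conductance: tonic level + linear drift + Bateman phasic responses."""

    tonic_us: float = 5.0
    drift_us_per_s: float = 0.005
    scr_amplitude_us: float = 0.5
    rise_s: float = 0.75
    decay_s: float = 2.0
    noise_sd_us: float = 0.01


@dataclass(frozen=True)
class SimConfig:
    """All generator knobs for one synthetic session.

    ``accuracy_offset_deg`` is a constant gaze bias (systematic calibration
    error); ``precision_sd_deg`` is the isotropic per-axis fixation noise SD
    (sample-to-sample jitter); ``loss_prob`` the per-sample probability of a
    device-invalid sample.
    """

    seed: int
    rate_hz: float = 150.0
    geometry: ScreenGeometry = DEFAULT_SCREEN
    accuracy_offset_deg: Tuple[float, float] = (0.6, 0.8)
    precision_sd_deg: float = 0.17
    loss_prob: float = 0.02
    timestamp_jitter_ms: float = 0.0
    saccade_latency_ms: Tuple[float, float] = (160.0, 30.0)
    main_sequence: MainSequenceParams = MainSequenceParams()
    pupil: PupilParams = PupilParams()
    affect: AffectParams = AffectParams()
    cardiac: CardiacParams = CardiacParams()
    sc: SCParams = SCParams()

    def __post_init__(self) -> None:
        if not (self.rate_hz > 0):
            raise ConfigError(f"rate_hz must be positive, got {self.rate_hz}")
        if not (0.0 <= self.loss_prob < 1.0):
            raise ConfigError(f"loss_prob must be in [0, 1), got {self.loss_prob}")
        if self.precision_sd_deg < 0:
            raise ConfigError("precision_sd_deg must be non-negative")
        if self.timestamp_jitter_ms < 0:
            raise ConfigError("timestamp_jitter_ms must be non-negative")
        for eq in (self.pupil.dark_mm, self.pupil.light_mm):
            if not (2.0 < eq < 10.0):
                raise ConfigError(f"pupil equilibrium {eq} mm outside plausible (2, 10)")
        if self.sc.scr_amplitude_us < 0:
            raise ConfigError("scr_amplitude_us must be non-negative")
        if not (0.04 <= self.cardiac.lf_freq_hz <= 0.15):
            raise ConfigError("lf_freq_hz must lie in the LF band 0.04-0.15 Hz")
        if not (0.15 <= self.cardiac.hf_freq_hz <= 0.4):
            raise ConfigError("hf_freq_hz must lie in the HF band 0.15-0.4 Hz")


@dataclass
class GroundTruth:
    """Generator-side true parameters, for parameter-recovery tests.

    Only the fields relevant to the generating task are populated.
    """

    accuracy_offset_deg: Optional[Tuple[float, float]] = None
    precision_sd_deg: Optional[float] = None
    loss_indices: Optional[np.ndarray] = None
    targets: Optional[pd.DataFrame] = None
    saccades: Optional[pd.DataFrame] = None
    epochs: Optional[pd.DataFrame] = None
    pupil_equilibria_mm: Optional[Tuple[float, float]] = None
    blink_intervals: Optional[pd.DataFrame] = None
    stimuli: Optional[pd.DataFrame] = None
    affect_coefs: Optional[dict] = None
    clean_beat_times: Optional[np.ndarray] = None
    clean_nn_ms: Optional[np.ndarray] = None
    sdnn_ms: Optional[float] = None
    rmssd_ms: Optional[float] = None
    artifact_flags: Optional[np.ndarray] = None
    scr_events: Optional[pd.DataFrame] = None


# ----------------------------------------------------------------------------
# fixation–saccade task
# ----------------------------------------------------------------------------

def _min_jerk(tau: np.ndarray) -> np.ndarray:
    """Normalized minimum-jerk position profile on tau in [0, 1]."""
    tau = np.clip(tau, 0.0, 1.0)
    return 10 * tau**3 - 15 * tau**4 + 6 * tau**5


def grid_targets_px(geometry: ScreenGeometry, spacing_deg: float = 11.0) -> np.ndarray:
    """Pixel coordinates of the 3×3 dot grid, centered on the screen.

    ``spacing_deg`` is the angular distance between orthogonally adjacent
    dots, so a center→edge target transition subtends exactly that angle
    and center→corner transitions √2 times it.
    """
    step_deg = spacing_deg
    cx, cy = geometry.width_px / 2.0, geometry.height_px / 2.0
    sx = step_deg / geometry.deg_per_px("horizontal")
    sy = step_deg / geometry.deg_per_px("vertical")
    pts = [(cx + i * sx, cy + j * sy) for j in (-1, 0, 1) for i in (-1, 0, 1)]
    return np.asarray(pts, float)  # index 4 is the central dot


def generate_fixation_saccade_session(
    config: SimConfig,
    visits_per_peripheral: int = 2,
    central_hold_s: Tuple[float, float] = (2.0, 5.0),
    peripheral_hold_s: Tuple[float, float] = (1.0, 1.5),
) -> Tuple[GazeRecording, pd.DataFrame, GroundTruth]:
    """Simulate the fixation–saccade task with known offsets, noise, and events.

    The target starts on the central dot and alternates center ↔ peripheral;
    all peripherals are exhausted (in random order) before any repeats, each
    visited ``visits_per_peripheral`` times. Every target transition elicits
    one saccade after a Gaussian latency, following a minimum-jerk position
    profile whose duration obeys the configured linear main sequence.

    Returns the gaze recording, a trial table (one row per fixation epoch),
    and the ground truth (true saccade windows, offset, noise SD, injected
    gap indices).
    """
    rng = np.random.default_rng(config.seed)
    geo = config.geometry
    targets = grid_targets_px(geo)
    center = targets[4]
    peripheral_idx = [i for i in range(9) if i != 4]

    # target schedule: center hold -> peripheral hold -> center hold -> ...
    order: list[int] = []
    for _ in range(visits_per_peripheral):
        order.extend(rng.permutation(peripheral_idx).tolist())

    segments = []  # (target_index, onset, offset, location)
    t_cursor = 0.0
    for p in order:
        hold_c = rng.uniform(*central_hold_s)
        segments.append((4, t_cursor, t_cursor + hold_c, "central"))
        t_cursor += hold_c
        hold_p = rng.uniform(*peripheral_hold_s)
        segments.append((p, t_cursor, t_cursor + hold_p, "peripheral"))
        t_cursor += hold_p
    final_hold = rng.uniform(*central_hold_s)
    segments.append((4, t_cursor, t_cursor + final_hold, "final_central"))
    duration = t_cursor + final_hold

    # true saccades: one per target transition
    lat_mu, lat_sd = config.saccade_latency_ms
    ms = config.main_sequence
    sacc_rows = []
    moves = []  # (t_start, t_end, from_xy, to_xy)
    prev_target = 4
    for (tgt, onset, _, _) in segments[1:]:
        a_deg = distance_deg(tuple(targets[prev_target]), tuple(targets[tgt]), geo)
        latency = max(rng.normal(lat_mu, lat_sd), 40.0) / 1000.0
        dur_s = (ms.slope_ms_per_deg * a_deg + ms.intercept_ms) / 1000.0
        t_start = onset + latency
        moves.append((t_start, t_start + dur_s, targets[prev_target], targets[tgt]))
        sacc_rows.append(
            dict(
                target_onset=onset,
                onset_time=t_start,
                offset_time=t_start + dur_s,
                amplitude_deg=a_deg,
                duration_ms=dur_s * 1000.0,
                latency_ms=latency * 1000.0,
                from_idx=prev_target,
                to_idx=tgt,
            )
        )
        prev_target = tgt

    # sample clock
    period = 1.0 / config.rate_hz
    n = int(math.floor(duration / period)) + 1
    t = np.arange(n) * period
    if config.timestamp_jitter_ms > 0:
        jitter = rng.normal(0.0, config.timestamp_jitter_ms / 1000.0, n)
        np.clip(jitter, -0.45 * period, 0.45 * period, out=jitter)
        t = t + jitter

    # noiseless eye position: piecewise constant + min-jerk movements
    x = np.full(n, center[0])
    y = np.full(n, center[1])
    seg_bounds = [s[1] for s in segments] + [duration]
    tgt_per_seg = [s[0] for s in segments]
    seg_of_sample = np.clip(np.searchsorted(seg_bounds, t, side="right") - 1, 0,
                            len(segments) - 1)
    for i, s in enumerate(seg_of_sample):
        x[i], y[i] = targets[tgt_per_seg[s]]
    # during each movement, override with the min-jerk trajectory
    for (m_start, m_end, frm, to) in moves:
        in_flight = (t >= m_start) & (t < m_end)
        tau = (t[in_flight] - m_start) / (m_end - m_start)
        prof = _min_jerk(tau)
        x[in_flight] = frm[0] + (to[0] - frm[0]) * prof
        y[in_flight] = frm[1] + (to[1] - frm[1]) * prof
    # samples between a target change and that transition's saccade onset
    # still fixate the *previous* target (latency period)
    for row, (m_start, m_end, frm, to) in zip(sacc_rows, moves):
        waiting = (t >= row["target_onset"]) & (t < m_start)
        x[waiting] = frm[0]
        y[waiting] = frm[1]

    # truth saccade sample windows: endpoints exact on the noiseless path
    for row, (m_start, m_end, frm, to) in zip(sacc_rows, moves):
        row["onset_idx"] = int(np.searchsorted(t, m_start, side="right") - 1)
        row["offset_idx"] = int(min(np.searchsorted(t, m_end, side="left"), n - 1))

    # accuracy offset (deg -> px per axis) and precision noise
    off_x = config.accuracy_offset_deg[0] / geo.deg_per_px("horizontal")
    off_y = config.accuracy_offset_deg[1] / geo.deg_per_px("vertical")
    sd_x = config.precision_sd_deg / geo.deg_per_px("horizontal")
    sd_y = config.precision_sd_deg / geo.deg_per_px("vertical")
    x = x + off_x + rng.normal(0.0, sd_x, n) if sd_x > 0 else x + off_x
    y = y + off_y + rng.normal(0.0, sd_y, n) if sd_y > 0 else y + off_y

    valid = rng.random(n) >= config.loss_prob
    loss_idx = np.flatnonzero(~valid)
    x = np.where(valid, x, np.nan)
    y = np.where(valid, y, np.nan)

    samples = pd.DataFrame(
        {"t": t, "x_px": x, "y_px": y, "valid": valid, "pupil_mm": np.nan}
    )
    rec = GazeRecording(samples, geo, nominal_rate_hz=config.rate_hz)

    trials = pd.DataFrame(
        [
            dict(
                trial_id=i,
                target_x_px=targets[tgt][0],
                target_y_px=targets[tgt][1],
                onset=onset,
                offset=offset,
                location="central" if loc != "peripheral" else "peripheral",
                block=0,
            )
            for i, (tgt, onset, offset, loc) in enumerate(segments)
        ]
    )
    truth = GroundTruth(
        accuracy_offset_deg=config.accuracy_offset_deg,
        precision_sd_deg=config.precision_sd_deg,
        loss_indices=loss_idx,
        targets=pd.DataFrame(targets, columns=["x_px", "y_px"]),
        saccades=pd.DataFrame(sacc_rows),
    )
    return rec, trials, truth


# ----------------------------------------------------------------------------
# PLR task
# ----------------------------------------------------------------------------

def generate_plr_session(
    config: SimConfig,
    n_per_luminance: int = 12,
    epoch_s: float = 5.0,
) -> Tuple[GazeRecording, pd.DataFrame, GroundTruth]:
    """Simulate the pupillary light reflex task.

    Black and white full-screen backgrounds alternate every ``epoch_s``
    seconds (``n_per_luminance`` presentations each, black first). After the
    configured latency the pupil relaxes exponentially toward the
    luminance-dependent equilibrium; measurement noise and blink gaps are
    superimposed. Gaze fixates a central dot throughout.
    """
    rng = np.random.default_rng(config.seed)
    geo = config.geometry
    pp = config.pupil
    n_epochs = 2 * n_per_luminance
    duration = n_epochs * epoch_s
    period = 1.0 / config.rate_hz
    n = int(math.floor(duration / period))
    t = np.arange(n) * period

    onsets = np.arange(n_epochs) * epoch_s
    lum = np.array(["black", "white"] * n_per_luminance)[:n_epochs]
    eq_map = {"black": pp.dark_mm, "white": pp.light_mm}

    # effective equilibrium at each sample, delayed by the PLR latency
    eff_time = t - pp.latency_s
    epoch_of = np.clip(np.searchsorted(onsets, eff_time, side="right") - 1, 0, n_epochs - 1)
    eq = np.array([eq_map[lum[k]] for k in epoch_of])

    pupil = np.empty(n)
    pupil[0] = eq[0]
    if pp.tau_s <= 0:
        pupil = eq.astype(float).copy()
    else:
        decay = math.exp(-period / pp.tau_s)
        for i in range(1, n):
            pupil[i] = eq[i] + (pupil[i - 1] - eq[i]) * decay
    if pp.noise_sd_mm > 0:
        pupil = pupil + rng.normal(0.0, pp.noise_sd_mm, n)

    # gaze: central fixation dot
    cx, cy = geo.width_px / 2.0, geo.height_px / 2.0
    sd_x = config.precision_sd_deg / geo.deg_per_px("horizontal")
    sd_y = config.precision_sd_deg / geo.deg_per_px("vertical")
    x = cx + rng.normal(0.0, sd_x, n)
    y = cy + rng.normal(0.0, sd_y, n)
    valid = np.ones(n, bool)

    # blinks: short validity gaps with missing pupil
    blink_rows = []
    n_blinks = rng.poisson(pp.blink_rate_per_min * duration / 60.0)
    blink_len = max(int(round(pp.blink_duration_ms / 1000.0 / period)), 1)
    for start_t in np.sort(rng.uniform(0.5, duration - 0.5, n_blinks)):
        i0 = int(start_t / period)
        i1 = min(i0 + blink_len, n)
        valid[i0:i1] = False
        pupil[i0:i1] = np.nan
        x[i0:i1] = np.nan
        y[i0:i1] = np.nan
        blink_rows.append(dict(onset=t[i0], offset=t[min(i1, n - 1)],
                               duration_ms=(i1 - i0) * period * 1000.0))

    samples = pd.DataFrame({"t": t, "x_px": x, "y_px": y, "valid": valid, "pupil_mm": pupil})
    rec = GazeRecording(samples, geo, nominal_rate_hz=config.rate_hz)
    stim = pd.DataFrame(
        dict(epoch_id=np.arange(n_epochs), luminance=lum, onset=onsets,
             offset=onsets + epoch_s)
    )
    truth = GroundTruth(
        epochs=stim.copy(),
        pupil_equilibria_mm=(pp.dark_mm, pp.light_mm),
        blink_intervals=pd.DataFrame(blink_rows),
    )
    return rec, stim, truth


# ----------------------------------------------------------------------------
# affective picture task
# ----------------------------------------------------------------------------

def generate_affective_session(
    config: SimConfig, n_stimuli: int = 50
) -> Tuple[GazeRecording, pd.DataFrame, GroundTruth]:
    """Simulate the affective picture task.

    Each trial is a fixation cross of uniform 7–15 s followed by a 6 s image.
    Per-image arousal ratings (−10..+10) and mean brightness (0..1) are drawn
    uniformly; the stimulus-locked pupil level is
    ``baseline + β_a·arousal − β_b·brightness + ε`` with the coefficients
    recorded in the ground truth.
    """
    if n_stimuli < 1:
        raise ConfigError("n_stimuli must be >= 1")
    rng = np.random.default_rng(config.seed)
    geo = config.geometry
    ap = config.affect
    period = 1.0 / config.rate_hz

    rows = []
    t_cursor = 0.0
    for i in range(n_stimuli):
        fix = rng.uniform(7.0, 15.0)
        arousal = rng.uniform(-10.0, 10.0)
        brightness = rng.uniform(0.0, 1.0)
        trial_noise = rng.normal(0.0, ap.noise_sd_mm)
        level = ap.baseline_mm + ap.arousal_coef * arousal - ap.brightness_coef * brightness
        rows.append(
            dict(
                trial_id=i,
                fix_onset=t_cursor,
                stim_onset=t_cursor + fix,
                stim_offset=t_cursor + fix + 6.0,
                arousal=arousal,
                brightness=brightness,
                true_level_mm=level + trial_noise,
            )
        )
        t_cursor += fix + 6.0
    stim = pd.DataFrame(rows)

    duration = t_cursor
    n = int(math.floor(duration / period))
    t = np.arange(n) * period
    pupil = np.full(n, ap.baseline_mm)
    for r in rows:
        mask = (t >= r["stim_onset"]) & (t < r["stim_offset"])
        pupil[mask] = r["true_level_mm"]
    pupil = pupil + rng.normal(0.0, 0.01, n)  # small per-sample measurement noise

    cx, cy = geo.width_px / 2.0, geo.height_px / 2.0
    sd_x = config.precision_sd_deg / geo.deg_per_px("horizontal")
    sd_y = config.precision_sd_deg / geo.deg_per_px("vertical")
    samples = pd.DataFrame(
        {
            "t": t,
            "x_px": cx + rng.normal(0.0, sd_x, n),
            "y_px": cy + rng.normal(0.0, sd_y, n),
            "valid": np.ones(n, bool),
            "pupil_mm": pupil,
        }
    )
    rec = GazeRecording(samples, geo, nominal_rate_hz=config.rate_hz)
    truth = GroundTruth(
        stimuli=stim.copy(),
        affect_coefs=dict(
            baseline_mm=ap.baseline_mm,
            arousal_coef=ap.arousal_coef,
            brightness_coef=ap.brightness_coef,
            noise_sd_mm=ap.noise_sd_mm,
        ),
    )
    return rec, stim, truth


# ----------------------------------------------------------------------------
# cardiac
# ----------------------------------------------------------------------------

def generate_nn_series(config: SimConfig, duration_s: float) -> Tuple[NNSeries, GroundTruth]:
    """Generate beat times whose IBIs carry LF and HF sinusoidal modulation.

    ``IBI(t) = mean + A_LF·sin(2π f_LF t) + A_HF·sin(2π f_HF t) + ε``,
    with beat times the cumulative sum of successive IBIs. If
    ``artifact_rate > 0``, beats are corrupted (half deleted = missed beat,
    half mid-interval insertions = spurious beat) and the affected intervals
    are flagged in the ground truth.
    """
    if duration_s <= 0:
        raise ConfigError("duration_s must be positive")
    cp = config.cardiac
    rng = np.random.default_rng(config.seed)

    beats = [0.0]
    while beats[-1] < duration_s:
        tk = beats[-1]
        ibi = (
            cp.mean_ibi_ms
            + cp.lf_amp_ms * math.sin(2 * math.pi * cp.lf_freq_hz * tk)
            + cp.hf_amp_ms * math.sin(2 * math.pi * cp.hf_freq_hz * tk)
            + (rng.normal(0.0, cp.noise_sd_ms) if cp.noise_sd_ms > 0 else 0.0)
        )
        if ibi <= 0:
            raise ConfigError("generated IBI <= 0; reduce amplitudes/noise")
        beats.append(tk + ibi / 1000.0)
    clean = np.array(beats)
    clean_nn = np.diff(clean) * 1000.0

    corrupted = clean.copy()
    if cp.artifact_rate > 0:
        keep = np.ones(len(clean), bool)
        inserts = []
        for k in range(1, len(clean) - 1):
            if rng.random() < cp.artifact_rate:
                if rng.random() < 0.5:
                    keep[k] = False  # missed beat
                else:
                    inserts.append(0.5 * (clean[k] + clean[k + 1]))  # spurious
        corrupted = np.sort(np.concatenate([clean[keep], np.array(inserts)]))

    rr = np.diff(corrupted) * 1000.0
    # flag corrupted intervals: any interval whose endpoints are not a
    # consecutive pair of clean beats
    clean_set = {round(b, 9) for b in clean}
    idx_of = {round(b, 9): i for i, b in enumerate(clean)}
    flags = np.zeros(len(rr), bool)
    for k in range(len(rr)):
        a, b = round(corrupted[k], 9), round(corrupted[k + 1], 9)
        ok = a in clean_set and b in clean_set and idx_of.get(b, -2) - idx_of.get(a, 9) == 1
        flags[k] = not ok

    nn = NNSeries(beat_times=corrupted)
    truth = GroundTruth(
        clean_beat_times=clean,
        clean_nn_ms=clean_nn,
        sdnn_ms=float(np.std(clean_nn, ddof=1)) if len(clean_nn) > 1 else 0.0,
        rmssd_ms=float(np.sqrt(np.mean(np.diff(clean_nn) ** 2)))
        if len(clean_nn) > 1
        else 0.0,
        artifact_flags=flags,
    )
    return nn, truth


def render_pulse_waveform(
    nn: NNSeries, rate_hz: float, bump_sd_s: float = 0.05, amplitude: float = 1.0
) -> PhysioTrace:
    """Render a smooth PPG-like waveform: one Gaussian bump per beat.

    Peak times coincide with beat times (to within the sample grid).
    Raises if the sampling rate cannot separate beats (shortest interval
    spanning fewer than 2 samples).
    """
    if nn.n_beats == 0:
        raise ConfigError("cannot render a waveform from an empty beat list")
    if nn.n_beats > 1 and np.min(np.diff(nn.beat_times)) < 2.0 / rate_hz:
        raise ConfigError("sampling rate too low to separate beats")
    # pad both ends so every beat is an interior local maximum
    t0 = nn.beat_times[0] - 1.0
    duration = nn.beat_times[-1] + 1.0 - t0
    n = int(duration * rate_hz)
    t = t0 + np.arange(n) / rate_hz
    v = np.zeros(n)
    half = 5.0 * bump_sd_s
    for b in nn.beat_times:
        i0 = max(int((b - half - t0) * rate_hz), 0)
        i1 = min(int((b + half - t0) * rate_hz) + 1, n)
        v[i0:i1] += amplitude * np.exp(-0.5 * ((t[i0:i1] - b) / bump_sd_s) ** 2)
    return PhysioTrace(t=t, value=v, rate_hz=rate_hz, units="au")


# ----------------------------------------------------------------------------
# skin conductance
# ----------------------------------------------------------------------------

def bateman(t: np.ndarray, rise_s: float, decay_s: float) -> np.ndarray:
    """Bi-exponential SCR kernel ``exp(-t/decay) - exp(-t/rise)`` for t >= 0."""
    t = np.asarray(t, float)
    out = np.zeros_like(t)
    pos = t >= 0
    out[pos] = np.exp(-t[pos] / decay_s) - np.exp(-t[pos] / rise_s)
    return out


def bateman_peak(rise_s: float, decay_s: float) -> Tuple[float, float]:
    """(time, height) of the Bateman kernel's maximum (closed form)."""
    t_star = rise_s * decay_s / (decay_s - rise_s) * math.log(decay_s / rise_s)
    h = math.exp(-t_star / decay_s) - math.exp(-t_star / rise_s)
    return t_star, h


def generate_sc_trace(
    config: SimConfig,
    event_times: Sequence[float],
    duration_s: Optional[float] = None,
    rate_hz: Optional[float] = None,
) -> Tuple[PhysioTrace, GroundTruth]:
    """Skin-conductance trace: tonic level + linear drift + Bateman SCRs + noise.

    Each event contributes ``a · (e^(−t/decay) − e^(−t/rise))`` starting at
    its event time; the ground truth records, per event, the coefficient and
    the resulting closed-form peak amplitude.
    """
    sp = config.sc
    rng = np.random.default_rng(config.seed)
    rate = rate_hz if rate_hz is not None else config.rate_hz
    event_times = np.sort(np.asarray(list(event_times), float))
    if duration_s is None:
        duration_s = (event_times[-1] + 20.0) if len(event_times) else 60.0
    if len(event_times) and (event_times[0] < 0 or event_times[-1] >= duration_s):
        raise ConfigError("event times must lie within the trace duration")

    n = int(duration_s * rate)
    t = np.arange(n) / rate
    v = sp.tonic_us + sp.drift_us_per_s * t
    t_star, h_star = bateman_peak(sp.rise_s, sp.decay_s)
    rows = []
    for e in event_times:
        v = v + sp.scr_amplitude_us * bateman(t - e, sp.rise_s, sp.decay_s)
        rows.append(
            dict(
                event_time=e,
                coefficient_us=sp.scr_amplitude_us,
                peak_amplitude_us=sp.scr_amplitude_us * h_star,
                peak_latency_s=t_star,
            )
        )
    if sp.noise_sd_us > 0:
        v = v + rng.normal(0.0, sp.noise_sd_us, n)
    trace = PhysioTrace(t=t, value=v, rate_hz=rate, units="uS")
    truth = GroundTruth(scr_events=pd.DataFrame(rows))
    return trace, truth
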