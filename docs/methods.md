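# Methods

`gazephys` implements the data-quality and signal-processing battery used to
characterise a low-cost remote eye-tracker (150 Hz, screen-based) paired
with a finger-worn unit recording photoplethysmographic pulse and skin
conductance. Because real participant recordings are not bundled, every
analysis is exercised against a synthetic-session generator with known
ground truth; this note describes the models, the defaults and their units,
the numerical choices, and what the parameter-recovery results do and do
not establish about real data.

## Geometry

Gaze is reported in screen pixels (origin top-left, y down, continuous).
Conversions to degrees of visual angle use the exact form
`2·atan(size/2d)` for full-screen extents and the central linear
approximation `extent_px · (axis extent in deg / axis pixels)` for
on-screen distances — the arithmetic behind "40 px ≈ 1°" on a
53 × 30 cm, 1920 × 1080 display viewed at 62.45 cm (45.99° × 27.01°).
The linear factor overestimates eccentric distances by < 2% inside the
central 20°; per-sample eye-to-screen distance compensation is not
attempted because the device does not stream distance.

## Synthetic sessions

The generator reproduces the structure of three tasks. All randomness
comes from a single integer seed; identical configuration gives
bit-identical output.

**Fixation–saccade task.** A 3×3 dot grid centred on the screen with 11°
between orthogonally adjacent dots, so centre→edge transitions subtend 11°
and centre→corner 15.6°. The target alternates centre ↔ peripheral,
exhausting all eight peripherals in random order before any repeats (two
visits each by default); central holds are uniform 2–5 s, peripheral holds
uniform 1.0–1.5 s (a choice; only the central hold range is prescribed by
the task design). Each target transition elicits one saccade after a
Gaussian latency (mean 160 ms, SD 30 ms, floored at 40 ms) following a
minimum-jerk position profile whose duration obeys a linear main sequence,
`duration = 2.2 ms/° · amplitude + 21 ms` — standard small-saccade
kinematics producing near-linear amplitude–duration and
amplitude–peak-velocity relations. Gaze during fixation is target +
constant bias (`accuracy_offset_deg`, default (0.6, 0.8)°, magnitude 1.0°,
the order of typical remote-tracker accuracy) + isotropic Gaussian noise
(`precision_sd_deg`, default 0.17° per axis, chosen so the implied RMS
sample-to-sample precision ≈ 0.24° matches what such devices deliver).
Samples are marked device-invalid i.i.d. with `loss_prob` (default 0.02).
Timestamp jitter is off by default; when enabled it is Gaussian on the
1/150 s grid, clipped at ±45% of a period to preserve monotonicity.

**PLR task.** 24 alternating full-screen black/white epochs of 5 s (12
each, black first). The pupil relaxes exponentially (τ = 0.4 s) toward a
luminance-dependent equilibrium (dark 6 mm, light 4 mm) after a 200 ms
latency, plus 0.05 mm measurement noise and Poisson blinks (4/min, 100 ms)
that appear as validity gaps with missing pupil.

**Affective task.** Per trial: uniform 7–15 s fixation, then a 6 s
stimulus whose arousal rating (uniform −10..+10) and mean brightness
(uniform 0..1) set the stimulus-locked pupil level,
`baseline + 0.02·arousal − 0.5·brightness + ε` (mm, ε SD 0.05).

**Cardiac.** `IBI(t) = 900 + 30·sin(2π·0.10·t) + 20·sin(2π·0.25·t) + ε`
ms (ε SD 10 ms); beat times are the cumulative sum, which places the
modulation inside the canonical LF (0.04–0.15 Hz) and HF (0.15–0.4 Hz)
bands. Optional artifacts delete a beat (missed) or insert one
mid-interval (spurious), each with probability `artifact_rate/2` per beat,
and are flagged in the ground truth. The pulse waveform is one Gaussian
bump (SD 50 ms) per beat at 150 Hz, padded 1 s at both ends so every beat
is an interior maximum.

**Skin conductance.** Tonic level 5 µS + 0.005 µS/s drift + per-event
Bateman kernels `a·(e^(−t/2.0) − e^(−t/0.75))` (coefficient a = 0.5 µS;
closed-form peak 0.347·a at 1.18 s) + 0.01 µS noise at 150 Hz.

What the generator does **not** emulate: pupil foreshortening and
gaze-position artifacts, saccadic overshoot/glissades, head movement,
correlated (pink) gaze noise, respiratory and movement artifacts in pulse
and SC, and real-image luminance. Recovery results therefore demonstrate
the correctness of the analysis arithmetic under the stated noise models,
not robustness to every failure mode of real recordings.

## Event detection

Per-sample angular velocity is the backward difference
`distance(sᵢ₋₁, sᵢ)/Δt`; it is undefined for the first sample and across
device-invalid samples (gaps are never bridged by velocity). The saccade
threshold is `median(v) + 5·MAD(v)` per recording, with the raw MAD (no
1.4826 consistency constant — the plain reading of "5 median absolute
deviations"; pass `n_mad` to rescale). A run of k consecutive
above-threshold velocities is a saccade if `k·period ≥ 20 ms` (three
sample periods at 150 Hz); shorter runs are relabelled fixation. Runs
separated by at most two below-threshold valid samples are merged first,
provided one side is a multi-sample run — this keeps a one-sample velocity
dip from splitting a saccade while preventing isolated single-sample noise
exceedances from chaining into spurious detections. Gaps split events: no
fixation or saccade spans an invalid sample.

Measured behaviour on synthetic sessions (16 transitions, 0.3° per-axis
noise, no loss): the detected count equals the true count on 95 of 100
seeds; the remaining seeds miss one short saccade whose above-threshold
run never reaches three samples. At the default 0.17° noise the detector
is exact except when an injected invalid sample lands inside a saccade and
splits it below the duration minimum — the documented consequence of the
gap rule, not a detection error.

## Quality metrics

Inter-sample statistics report mean/SD and median/MAD of Δt (ms) and the
proportion of intervals exceeding two nominal periods. Loss is the
per-trial proportion of invalid plus off-screen samples, with off-screen
defined on half-open bounds `[0, width_px) × [0, height_px)`; the two
components are reported separately and an empty trial yields NaN, not 0.

Accuracy: trials are trimmed 250 ms at both ends; per-sample horizontal,
vertical and global errors to the target are computed in degrees (the
global error is the Euclidean norm of the axis errors, so
`A_G² = A_H² + A_V²` holds exactly per sample); within each trial and
metric, samples beyond 4 raw MADs from the median are dropped (MAD = 0
drops nothing), then trial means are taken. Outlier filtering can be
disabled (`outlier_k=None`) to check robustness. Precision: fixations
longer than 80 ms whose span lies inside the trimmed window contribute the
RMS of successive axis steps (P_H, P_V) and of Euclidean step lengths
(P_G ≥ max(P_H, P_V)); pairs spanning a gap are excluded, and fixation
values are averaged per trial. For i.i.d. per-axis noise of SD σ the
expected P_H is σ√2, which the pipeline recovers within a few percent.

Drift over trials is fit by OLS on centred orthonormal linear and
quadratic polynomials of trial index plus a mean-centred block indicator;
the linear coefficient is also re-expressed as raw change per trial.
Mixed-effects inference is out of scope; per-participant OLS plus group
summaries replace it.

## Saccadometry

Amplitude is the chord between the onset and offset samples (not path
length); gain divides it by the target-to-target distance; starting and
landing errors are distances from onset/offset samples to the respective
target centres; latency is onset time minus target onset and may be
negative (anticipatory saccades are reported, not clamped); per-sample
velocities give the mean and peak. Curvature is the median over interior
samples of the unsigned angle at the onset point between the onset→offset
chord and the onset→sample vector — zero for collinear paths, invariant
to rotation and translation when the axis conversion factors are equal.
A transition is matched to the first detected saccade with onset inside
the new trial and amplitude ≥ 1°.

On noiseless sessions, gain and curvature are checked on the generator's
true event windows (last sample at/before movement onset to first at/after
offset), where both are exact; detector-derived windows necessarily clip
the sub-threshold creep at the movement's tails, biasing gain low by
a few percent at 150 Hz — a sampling property, not an implementation
artifact, and the reason observed gains below 1 are expected from such
trackers.

## Pupillometry

Diameters outside 2–10 mm are flagged missing; missing runs up to 150 ms
(measured between flanking valid samples) are linearly interpolated, never
extrapolated at trace edges. Baseline correction is subtractive per trial:
the baseline is the median over the last 20 samples of the preceding trial
and the first 20 of the current one (40 samples ≈ 267 ms at 150 Hz; the
window is defined by sample count, not milliseconds). The first trial uses
only its own first 20 samples and is flagged; a fully missing window marks
the trial uncorrectable.

With 5 s luminance alternation the 40-sample window straddles the
luminance change, and because the ~200 ms response latency keeps the first
20 samples of each epoch at the previous equilibrium, the baseline equals
the preceding epoch's steady state. Mean corrected pupil over each epoch's
steady portion (2 s after onset to offset) is then ≈ +gap in dark epochs
and ≈ −gap in light epochs, so the PLR effect is summarised as the
constriction amplitude `(dark − light)/2` of per-condition means — an
estimator of the equilibrium gap — together with the signed white−black
difference (negative: constriction to light) and the R² of a two-level
fixed-effects fit over epoch means. The first (flagged) epoch is excluded.

Arousal/brightness modulation is estimated by OLS of stimulus-locked
baseline-corrected means on mean-centred predictors; raw and standardized
coefficients are both returned. Crossed random effects are out of scope.

## Cardiac metrics

Pulse traces are zero-phase Butterworth low-pass filtered (default 15 Hz;
valid 10–20 Hz below Nyquist). Beats are supra-threshold local maxima with
a 250 ms refractory period (a ceiling of 240 bpm): the global method
thresholds at half the trace range; the local method at half the running
2 s window range, robust to slow drift. Peak times are refined by
parabolic interpolation through three samples, giving sub-millisecond beat
times from a 150 Hz trace.

RR intervals beyond median ± 4 raw MADs of the recording's own
distribution are flagged — a deliberately simple distribution-threshold
rule (doubled or halved intervals from missed/spurious beats sit far
outside the robust band) — and replaced by cubic-spline interpolation over
beat index to form the NN series. Time-domain metrics: SDNN (sample SD,
ddof 1), RMSSD, NN50 (count of successive differences > 50 ms) and pNN50
(the same as a percentage of n−1 pairs). Heart rate is
`60000 / (3-beat moving mean of NN)`. Frequency-domain: the NN tachogram
(NN attributed to its closing beat time) is cubic-spline resampled at
4 Hz, mean-removed, and Welch-estimated with 64 s segments at 50% overlap
and linear detrending; LF and HF are the integrated absolute powers over
0.04–0.15 Hz and 0.15–0.4 Hz (ms²). Records must span at least one LF
cycle (25 s); the default problem size for recovery runs is a 300 s
resting record (≈ 335 beats), where end-to-end SDNN recovery through
rendering, filtering, detection and correction is within a fraction of a
percent.

## Electrodermal metrics

Traces are FIR anti-alias filtered and decimated to 10 Hz (cascaded
factors; the tonic mean is removed before filtering and restored after, to
avoid zero-padding edge transients), then smoothed with a Gaussian kernel
whose SD adapts between 2 and 8 samples: local noise SD is estimated from
second differences (which cancel the tonic trend and near-linear SCR
slopes; white-noise second-difference variance is 6σ²) and mapped linearly
to kernel width, saturating at a reference noise SD of 0.05 µS. The
absolute reference means a clean SCR is smoothed minimally rather than
flattened. The event-related response is `max` over 1–5 s post-event minus
the mean over 1 s pre-event (a window-mean variant is exposed); no
tonic/phasic deconvolution is performed, so the measure is a documented
proxy for decomposition-based phasic amplitude. Device agreement reports
Pearson and Kendall rank correlations over paired aggregates, both
invariant to affine rescaling — appropriate when one device's signal spans
a compressed range.

## Numerical and interface choices

- Times are float seconds from session start; every interval rule is
  half-open `[onset, offset)`.
- CSV floats are written with shortest round-trip `repr` and read with
  round-trip parsing, so write→read is bit-exact (pixel-mode gaze files
  and physio files).
- Degenerate inputs fail loudly: non-monotone time, all-undefined
  velocities, single-luminance PLR data, zero expected saccade amplitude,
  collinear predictors, sub-Nyquist filter requests and too-short records
  raise typed errors rather than returning silently wrong numbers.
- MAD = 0 disables outlier dropping (accuracy) and artifact flagging (RR),
  never the reverse.
- The acceptance script (`scripts/acceptance.py`) re-runs all of the above
  at the problem sizes stated here (one fixation–saccade session per
  check, 50 affective stimuli, 300 s cardiac records, 30 s SC traces) and
  derives all sub-seeds from its `--seed` argument; the
  saccade-detection-count entry uses a fixed stress configuration (0.3°
  noise, no loss), whose seed-to-seed behaviour is documented above.

## Known limitations

- The detector's exact-count property degrades for saccades much below 9°
  or noise above ~0.3° per axis at 150 Hz; the 20 ms (3-sample) minimum is
  then the binding constraint.
- The PLR constriction estimator assumes strict luminance alternation and
  a response latency longer than the post-onset half of the baseline
  window; designs violating either need a pre-onset-only baseline.
- The IBI artifact rule is a threshold proxy; consecutive artifacts that
  shift the median, or artifacts exceeding ~half the flagged fraction,
  would need the full individual-threshold procedure it stands in for.
- Frequency-domain HRV on short (< 2 min) records is dominated by spectral
  leakage; the defaults assume ≥ 5 min resting data.
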