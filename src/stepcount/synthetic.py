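"""Labelled synthetic accelerometer signals with exact ground truth.

The generator is a parametric signal model, not a biomechanical one: it
reproduces the features of walking that the pipeline keys on, with knobs
aligned to the pipeline's thresholds.

Walking magnitude model (g units)::

    m(t) = 1 + sum_k (A_k / 2) * (1 + cos(2*pi*(t - t_k)/w)) * 1[|t - t_k| <= w/2]
             + ripple(t) + noise(t)

one raised-cosine pulse of height ``A_k = peak_amp +/- jitter`` and width
``w = pulse_width_frac * Ts`` per step, a small second-harmonic ripple
(<= 20% of peak_amp, tapered to zero outside the stepping span), and white
Gaussian sensor noise. Step times follow ``Ts * (1 + cv * z)``. The scalar
profile is embedded into three axes along one fixed random unit vector per
recording (the device's pocket pose), so the RMS magnitude recovers it
exactly.

False walking comes in two flavours: sustained band-limited vibration
around 1 g (vehicle, leg tremor) and short bursts of rapid aperiodic
transients (hand motion, pocket insertion) whose spacing sits below the
gait cadence band. Ground truth for false walking is always zero steps.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal as sps

from .errors import ConfigError
from .signal_io import AccelSeries, GroundTruth
from .state_profile import DEFAULT_TH_VIB, DEFAULT_TS, MotionState

#: Vibration-style false walking must stay below every state's th_vib.
_MIN_TH_VIB = min(DEFAULT_TH_VIB.values())

#: Per-state pulse height above 1 g. Chosen so that, *after* the mandatory
#: 3 Hz low-pass, every state clears the fixed dynamic-threshold margin
#: (0.15 g) and — deliberately — the prominence threshold of the *next
#: faster* state as well, so a window misclassified one state up does not
#: lose its steps; the resulting window means order SLOW < NORMAL < FAST.
DEFAULT_PEAK_AMP = {MotionState.SLOW: 0.40, MotionState.NORMAL: 0.60, MotionState.FAST: 0.70}

#: Pulse width as a fraction of the step period: faster gait spends a larger
#: share of the cycle accelerating, which also spreads the state window
#: means apart for classification.
DEFAULT_PULSE_FRAC = {MotionState.SLOW: 0.65, MotionState.NORMAL: 0.75, MotionState.FAST: 0.85}

_FALSE_KINDS = ("hand_motion", "pocket_insertion", "vehicle_vibration", "leg_tremor")
_VIBRATION_KINDS = ("vehicle_vibration", "leg_tremor")


@dataclass(frozen=True)
class WalkSpec:
    """Parameters of one constant-state synthetic walk."""

    state: MotionState = MotionState.NORMAL
    n_steps: int = 60
    step_period_mean: float | None = None  # default: the state's Ts
    step_period_cv: float = 0.05
    peak_amp: float | None = None  # default: per-state table above
    amp_jitter: float = 0.03
    noise_sd: float = 0.02
    seed: int = 0
    pulse_width_frac: float | None = None  # default: per-state table above
    ripple_frac: float = 0.10  # 2nd-harmonic ripple, fraction of peak_amp
    lead_s: float = 1.0  # still padding before/after the steps

    def resolved(self) -> "WalkSpec":
        """Fill state-dependent defaults."""
        return replace(
            self,
            step_period_mean=self.step_period_mean or DEFAULT_TS[self.state],
            peak_amp=self.peak_amp if self.peak_amp is not None else DEFAULT_PEAK_AMP[self.state],
            pulse_width_frac=self.pulse_width_frac or DEFAULT_PULSE_FRAC[self.state],
        )

    def __post_init__(self):
        if self.n_steps < 0:
            raise ConfigError("n_steps must be >= 0")
        for name in ("step_period_cv", "amp_jitter", "noise_sd", "ripple_frac", "lead_s"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0")
        if self.ripple_frac > 0.20:
            raise ConfigError("ripple_frac is capped at 0.20")


@dataclass(frozen=True)
class FalseWalkSpec:
    """Parameters of one device-moves-but-user-does-not-walk recording."""

    kind: str = "vehicle_vibration"
    duration: float = 20.0
    vib_amp: float = 0.05
    n_pseudo_events: int = 20
    seed: int = 0
    event_amp_range: tuple = (0.35, 0.6)  # session gesture intensity above 1 g
    event_amp_jitter: float = 0.04  # per-transient intensity jitter, g
    event_width: float = 0.25  # transient width, s
    event_spacing: tuple = (0.29, 0.34)  # s, below the gait cadence band

    def __post_init__(self):
        if self.kind not in _FALSE_KINDS:
            raise ConfigError(f"kind must be one of {_FALSE_KINDS}")
        if self.duration < 0 or self.vib_amp < 0 or self.n_pseudo_events < 0:
            raise ConfigError("duration, vib_amp and n_pseudo_events must be >= 0")
        if self.kind in _VIBRATION_KINDS and self.vib_amp >= _MIN_TH_VIB:
            raise ConfigError(
                f"vib_amp must stay below the smallest state th_vib ({_MIN_TH_VIB} g)"
            )
        lo, hi = self.event_spacing
        if not (0 < lo <= hi):
            raise ConfigError("event_spacing must be positive and ordered")


def _embed(t: np.ndarray, m: np.ndarray, fs: float, rng: np.random.Generator) -> AccelSeries:
    """Project a magnitude profile onto a fixed random unit orientation."""
    v = rng.normal(size=3)
    v /= np.linalg.norm(v)
    return AccelSeries(t=t, ax=m * v[0], ay=m * v[1], az=m * v[2], fs=fs, source_units="g")


def _pulse_train(
    t: np.ndarray, step_times: np.ndarray, amps: np.ndarray, width: float
) -> np.ndarray:
    """Sum of raised-cosine pulses of the given centres/heights/width."""
    m = np.zeros_like(t)
    half = width / 2.0
    for tc, a in zip(step_times, amps):
        lo, hi = np.searchsorted(t, [tc - half, tc + half])
        u = t[lo:hi] - tc
        m[lo:hi] += (a / 2.0) * (1.0 + np.cos(np.pi * u / half))
    return m


def walk_magnitude_profile(
    spec: WalkSpec, t: np.ndarray, step_times: np.ndarray, amps: np.ndarray
) -> np.ndarray:
    """Noise-free magnitude profile of a walk (baseline + pulses + ripple).

    Exposed so tests can verify generator self-consistency: the magnitude
    of a noise-free generated series must reproduce this profile exactly.
    """
    spec = spec.resolved()
    ts = spec.step_period_mean
    width = spec.pulse_width_frac * ts
    m = 1.0 + _pulse_train(t, step_times, amps, width)
    if len(step_times) and spec.ripple_frac > 0:
        # second harmonic of the cadence, tapered off over one period at
        # each end of the stepping span so still segments stay still
        span_lo, span_hi = step_times[0] - ts / 2, step_times[-1] + ts / 2
        env = np.clip((t - span_lo) / ts, 0, 1) * np.clip((span_hi - t) / ts, 0, 1)
        m += spec.ripple_frac * spec.peak_amp * env * np.sin(4 * np.pi * (t - step_times[0]) / ts)
    return m


def generate_walk(
    spec: WalkSpec, fs: float = 50.0, return_params: bool = False
):
    """Generate a constant-state walk and its exact ground truth.

    With ``return_params=True`` a third element is returned: a dict with the
    drawn ``step_times`` and per-step pulse ``amps``, so callers can rebuild
    the noise-free profile via :func:`walk_magnitude_profile`.
    """
    if fs < 20:
        raise ConfigError("fs must be >= 20 Hz")
    spec = spec.resolved()
    rng = np.random.default_rng(spec.seed)
    ts = spec.step_period_mean

    if spec.n_steps == 0:
        dur = max(2.0 * spec.lead_s, 2.0 / fs)
        t = np.arange(int(round(dur * fs)) + 1) / fs
        m = 1.0 + rng.normal(0.0, spec.noise_sd, size=len(t))
        out = _embed(t, np.clip(m, 0, None), fs, rng), GroundTruth(0, np.array([]))
        return (*out, {"step_times": np.array([]), "amps": np.array([])}) if return_params else out

    z = np.clip(rng.standard_normal(spec.n_steps - 1), -3, 3) if spec.n_steps > 1 else np.array([])
    intervals = ts * (1.0 + spec.step_period_cv * z)
    step_times = spec.lead_s + ts / 2 + np.concatenate([[0.0], np.cumsum(intervals)])
    amps = np.clip(rng.normal(spec.peak_amp, spec.amp_jitter, size=spec.n_steps), 0.05, None)

    dur = step_times[-1] + ts / 2 + spec.lead_s
    t = np.arange(int(round(dur * fs)) + 1) / fs
    m = walk_magnitude_profile(spec, t, step_times, amps)
    if spec.noise_sd > 0:
        m = m + rng.normal(0.0, spec.noise_sd, size=len(t))
    series = _embed(t, np.clip(m, 0, None), fs, rng)
    truth = GroundTruth(spec.n_steps, step_times)
    if return_params:
        return series, truth, {"step_times": step_times, "amps": amps}
    return series, truth


def generate_false_walk(spec: FalseWalkSpec, fs: float = 50.0) -> tuple[AccelSeries, GroundTruth]:
    """Generate a false-walking recording; ground truth is always 0 steps."""
    if fs < 20:
        raise ConfigError("fs must be >= 20 Hz")
    rng = np.random.default_rng(spec.seed)

    if spec.kind in _VIBRATION_KINDS:
        n = int(round(spec.duration * fs)) + 1 if spec.duration > 0 else 0
        if n == 0:
            empty = np.array([])
            return (
                AccelSeries(t=empty, ax=empty, ay=empty, az=empty, fs=fs),
                GroundTruth(0, np.array([])),
            )
        t = np.arange(n) / fs
        white = rng.normal(size=n)
        b, a = sps.butter(2, min(8.0, 0.45 * fs), btype="low", fs=fs)
        band = sps.filtfilt(b, a, white)
        band *= (spec.vib_amp / 2.0) / max(band.std(), 1e-12)  # excursions ~ +/- vib_amp
        m = 1.0 + band
        return _embed(t, np.clip(m, 0, None), fs, rng), GroundTruth(0, np.array([]))

    # burst of rapid aperiodic transients (hand shaking / pocket insertion)
    k = spec.n_pseudo_events
    if k == 0 or spec.duration == 0:
        if spec.duration == 0:
            empty = np.array([])
            return (
                AccelSeries(t=empty, ax=empty, ay=empty, az=empty, fs=fs),
                GroundTruth(0, np.array([])),
            )
        k = 0
    lo, hi = spec.event_spacing
    spacing = rng.uniform(lo, hi, size=max(k - 1, 0))
    centers = 1.0 + np.concatenate([[0.0], np.cumsum(spacing)]) if k else np.array([])
    # one gesture = one consistent intensity, ramping up and dying out:
    # a raised-cosine envelope over the first/last quarter of the burst
    intensity = rng.uniform(*spec.event_amp_range)
    ramp = max(1, k // 4)
    env = np.ones(k)
    up = 0.5 * (1 - np.cos(np.pi * (np.arange(ramp) + 0.5) / ramp))
    env[:ramp] = up
    env[k - ramp :] = up[::-1]
    amps = np.clip(intensity * env + rng.normal(0.0, spec.event_amp_jitter, size=k), 0.0, None)
    dur = max(spec.duration, (centers[-1] + 1.0) if k else spec.duration)
    t = np.arange(int(round(dur * fs)) + 1) / fs
    m = 1.0 + _pulse_train(t, centers, amps, spec.event_width)
    m += rng.normal(0.0, 0.01, size=len(t))
    return _embed(t, np.clip(m, 0, None), fs, rng), GroundTruth(0, np.array([]))


def generate_session(
    script: list, fs: float = 50.0, gap_s: float = 0.5, seed: int = 0
) -> tuple[AccelSeries, GroundTruth]:
    """Concatenate walk / false-walk segments with still gaps between them.

    Ground truth is the union of the segment truths, shifted to session
    time. Each segment keeps its own seed; the session seed only drives the
    noise in the inter-segment gaps.
    """
    if not script:
        raise ConfigError("session script needs at least one segment")
    rng = np.random.default_rng(seed)
    t_parts, a_parts = [], []
    times = []
    offset = 0.0
    total = 0
    for i, seg in enumerate(script):
        if isinstance(seg, WalkSpec):
            series, truth = generate_walk(seg, fs)
        elif isinstance(seg, FalseWalkSpec):
            series, truth = generate_false_walk(seg, fs)
        else:
            raise ConfigError(f"segment {i} is neither WalkSpec nor FalseWalkSpec")
        if len(series) == 0:
            continue
        t_parts.append(series.t + offset)
        a_parts.append(np.column_stack([series.ax, series.ay, series.az]))
        if truth.step_times is not None and len(truth.step_times):
            times.append(truth.step_times + offset)
        total += truth.true_step_count
        offset += series.t[-1] + 1.0 / fs
        if gap_s > 0 and i < len(script) - 1:
            ng = int(round(gap_s * fs))
            gm = 1.0 + rng.normal(0.0, 0.01, size=ng)
            v = rng.normal(size=3)
            v /= np.linalg.norm(v)
            t_parts.append(offset + np.arange(ng) / fs)
            a_parts.append(np.outer(gm, v))
            offset += ng / fs
    t = np.concatenate(t_parts)
    axyz = np.vstack(a_parts)
    series = AccelSeries(t=t, ax=axyz[:, 0], ay=axyz[:, 1], az=axyz[:, 2], fs=fs)
    all_times = np.concatenate(times) if times else np.array([])
    return series, GroundTruth(total, all_times)


def inject_pulse(
    series: AccelSeries, time: float, amp: float, width: float = 0.2
) -> AccelSeries:
    """Add one spurious raised-cosine transient to a generated recording.

    Used to reproduce the noisy-signal failure mode in which a tall false
    peak appears mid-stride. The pulse is added along the recording's own
    (fixed) orientation so the magnitude picks it up exactly.
    """
    m = np.sqrt(series.ax**2 + series.ay**2 + series.az**2)
    j = int(np.argmax(m))
    v = np.array([series.ax[j], series.ay[j], series.az[j]]) / m[j]
    extra = _pulse_train(series.t, np.array([time]), np.array([amp]), width)
    return AccelSeries(
        t=series.t,
        ax=series.ax + extra * v[0],
        ay=series.ay + extra * v[1],
        az=series.az + extra * v[2],
        fs=series.fs,
        source_units=series.source_units,
    )
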