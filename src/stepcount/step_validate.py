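"""Phase 4: step confirmation, pipeline orchestration and evaluation.

A Phase-3 peak becomes a confirmed step only when its timing and amplitude
look like gait:

* periodicity — the interval to the previously confirmed peak must fall in
  a cadence band (natural step periods cluster around 0.45-0.65 s); a peak
  arriving after a gap longer than the band restarts a walking bout and is
  accepted as the bout's first step;
* similarity — consecutive steps of the same leg (i.e. peaks two apart)
  have nearly equal amplitude; a peak whose amplitude differs too much from
  the last-but-one confirmed peak is rejected.

Rejection never cascades: a failing peak is dropped alone, never together
with the previously confirmed peaks it was compared against. This is what
keeps noisy recordings from being under-counted.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigError, DataError
from .peak_detect import (
    DynamicThresholdConfig,
    Peak,
    candidate_peaks,
    dynamic_threshold_filter,
    prominence_filter,
    vibration_filter,
)
from .preprocess import lowpass, magnitude
from .signal_io import AccelSeries
from .state_profile import (
    ClassifierConfig,
    MotionState,
    profile_for,
    states_per_sample,
)

#: Periodicity acceptance band (s): the 0.45-0.65 s natural step-period
#: range widened ~25% for inter-subject variability.
DEFAULT_T_MIN = 0.35
DEFAULT_T_MAX = 0.80

#: Similarity tolerance (g): clean strides jitter well below this; spikes
#: of twice the stride amplitude fail it.
DEFAULT_S_TOL = 0.3


@dataclass(frozen=True)
class ValidationConfig:
    t_min: float = DEFAULT_T_MIN
    t_max: float = DEFAULT_T_MAX
    s_tol: float = DEFAULT_S_TOL

    def __post_init__(self):
        if not (0 < self.t_min < self.t_max):
            raise ConfigError("need 0 < t_min < t_max")
        if self.s_tol <= 0:
            raise ConfigError("s_tol must be positive")


@dataclass(frozen=True)
class StepEvent:
    """A confirmed step: when it happened, in which state, how tall."""

    time: float
    state: MotionState
    amplitude: float
    interval_prev: float = float("nan")  # NaN for a bout's first step


@dataclass(frozen=True)
class EvalResult:
    """Detected-vs-true contrast: Error = |E - T| / T * 100%."""

    e: float
    t: float
    error_pct: float
    accuracy_pct: float


@dataclass(frozen=True)
class PipelineConfig:
    """Everything the end-to-end pipeline needs, with calibrated defaults."""

    cutoff_hz: float = 3.0
    classifier: ClassifierConfig = field(default_factory=ClassifierConfig)
    th_d: float = 0.15
    validation: ValidationConfig = field(default_factory=ValidationConfig)
    #: per-state overrides, e.g. {MotionState.SLOW: {"d": 16}}
    profile_overrides: dict = field(default_factory=dict)
    #: force every window into one state instead of classifying
    forced_state: MotionState | None = None


def periodicity(peak_a: Peak, peak_b: Peak, fs: float) -> float:
    """Interval between two peaks in seconds: (index_b - index_a) / fs.

    Computed from sample indices and the sampling rate rather than wall
    clock, so it is exact on the uniform grid.
    """
    if peak_b.index <= peak_a.index:
        raise DataError("peaks must be passed in increasing index order")
    return (peak_b.index - peak_a.index) / fs


def similarity(peak_i: Peak, peak_i2: Peak) -> float:
    """Same-leg amplitude similarity: -(|amp_{i+2} - amp_i|), g units.

    Zero means identical amplitudes; more negative means less alike.
    """
    return -abs(peak_i2.amplitude - peak_i.amplitude)


def validate(peaks: list[Peak], cfg: ValidationConfig | None = None, fs: float = 50.0) -> list[StepEvent]:
    """Confirm steps among time-ordered Phase-3 survivors.

    A peak is confirmed when (a) its interval to the previously confirmed
    peak lies within [t_min, t_max], or it starts a new bout (gap > t_max,
    or nothing confirmed yet); and (b) its amplitude is within s_tol of the
    last-but-one peak confirmed in the current bout (skipped while the bout
    has fewer than two confirmed steps). Rejected peaks are dropped alone.
    """
    cfg = cfg or ValidationConfig()
    events: list[StepEvent] = []
    last: Peak | None = None
    bout: list[Peak] = []
    for p in peaks:
        if last is not None and p.index <= last.index:
            raise DataError("peaks must be strictly increasing in index")
        interval = math.nan if last is None else periodicity(last, p, fs)
        if last is None or interval > cfg.t_max:
            # bout start: stream restart after a pause (or very first peak)
            bout = [p]
            last = p
            events.append(StepEvent(p.time, p.state, p.amplitude, math.nan))
            continue
        if interval < cfg.t_min:
            continue
        if len(bout) >= 2 and -similarity(bout[-2], p) > cfg.s_tol:
            continue
        bout.append(p)
        last = p
        events.append(StepEvent(p.time, p.state, p.amplitude, interval))
    return events


def count_steps(
    series: AccelSeries,
    config: PipelineConfig | None = None,
    return_peaks: bool = False,
):
    """Run the four-phase pipeline on a recording.

    Phase 1 computes the magnitude and low-pass filters it; Phase 2 labels
    2 s windows by mean magnitude and maps the labels back to samples;
    Phase 3 detects peaks per contiguous state segment with that state's
    parameter bundle; Phase 4 validates periodicity and similarity globally.

    Returns the confirmed steps and a Counter of steps per state; with
    ``return_peaks=True`` also the Phase-3 survivors (for debugging dumps).
    """
    config = config or PipelineConfig()
    if len(series) < 3:
        return ([], Counter(), []) if return_peaks else ([], Counter())
    mag = lowpass(magnitude(series), config.cutoff_hz)

    if config.forced_state is not None:
        sample_states = np.array([config.forced_state] * len(mag), dtype=object)
    else:
        sample_states = states_per_sample(mag, config.classifier)

    # Phase 3 per state, on the full signal: a peak is a candidate under its
    # own state's d and is filtered with that state's thresholds, but every
    # window (prominence, dynamic threshold) sees the whole recording, so
    # classification boundaries do not truncate the evidence.
    peaks: list[Peak] = []
    for state in MotionState:
        mask = sample_states == state
        if not mask.any():
            continue
        profile = profile_for(state, mag.fs, config.profile_overrides.get(state))
        cand = [p for p in candidate_peaks(mag, profile.d) if mask[p.index]]
        cand = prominence_filter(mag, cand, profile.h, profile.win_size)
        cand = dynamic_threshold_filter(
            mag, cand, DynamicThresholdConfig(th_d=config.th_d, win_size=profile.win_size)
        )
        cand = vibration_filter(cand, profile.th_vib)
        for p in cand:
            p.state = state
        peaks.extend(cand)
    peaks.sort(key=lambda p: p.index)

    events = validate(peaks, config.validation, mag.fs)
    counts = Counter(e.state for e in events)
    return (events, counts, peaks) if return_peaks else (events, counts)


def evaluate(e: float, t: float) -> EvalResult:
    """Error of a detected count E against the true count T (percent)."""
    if t <= 0:
        raise ConfigError("true step count T must be positive")
    error = abs(e - t) / t * 100.0
    return EvalResult(e=e, t=t, error_pct=error, accuracy_pct=100.0 - error)
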