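"""Phase 2: walking-state classification and per-state parameters.

Faster walking produces a larger mean acceleration magnitude, so a sliding
window mean with two thresholds (M1, M2) separates slow, normal and fast
walking. Every later stage is parameterised per state: the minimal peak
distance d shrinks with cadence while the prominence and vibration
thresholds grow with the more vigorous signal.

Per-state defaults
------------------
==========  ====  =======  ==========  =======
state        d     H (g)   th_vib (g)  Ts (s)
==========  ====  =======  ==========  =======
SLOW         14    0.20      0.08       0.635
NORMAL       12    0.25      0.10       0.507
FAST         10    0.35      0.15       0.469
==========  ====  =======  ==========  =======

The dynamic-threshold window size is derived from the mean step period:
``win_size = round(Ts * fs) - 1`` samples.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

import numpy as np

from .errors import ConfigError
from .preprocess import MagnitudeSeries


class MotionState(enum.Enum):
    SLOW = "slow"
    NORMAL = "normal"
    FAST = "fast"


#: Minimal peak distance in samples (at the nominal 50 Hz rate).
DEFAULT_D = {MotionState.SLOW: 14, MotionState.NORMAL: 12, MotionState.FAST: 10}

#: Minimal peak prominence threshold H, g units.
DEFAULT_H = {MotionState.SLOW: 0.20, MotionState.NORMAL: 0.25, MotionState.FAST: 0.35}

#: Vibration-elimination threshold Th_vib, g units above 1 g.
DEFAULT_TH_VIB = {MotionState.SLOW: 0.08, MotionState.NORMAL: 0.10, MotionState.FAST: 0.15}

#: Mean step period Ts, seconds.
DEFAULT_TS = {MotionState.SLOW: 0.635, MotionState.NORMAL: 0.507, MotionState.FAST: 0.469}

# The M1/M2 boundaries are calibrated to the synthetic generator's analytic
# window means for the three cadence presets (~1.13 / 1.23 / 1.30 g); real
# devices and carrying positions will need their own calibration, so both
# are prominent config surface. See docs/methods.md.
DEFAULT_M1 = 1.18
DEFAULT_M2 = 1.26
DEFAULT_WINDOW_S = 2.0


@dataclass(frozen=True)
class ClassifierConfig:
    """Mean-magnitude thresholds (g) and window length for state labelling."""

    m1: float = DEFAULT_M1
    m2: float = DEFAULT_M2
    window_s: float = DEFAULT_WINDOW_S

    def __post_init__(self):
        if not (0 < self.m1 < self.m2):
            raise ConfigError("need 0 < M1 < M2")
        if self.window_s <= 0:
            raise ConfigError("window_s must be positive")


@dataclass(frozen=True)
class StateProfile:
    """Parameter bundle handed to peak detection for one walking state."""

    state: MotionState
    d: int
    h: float
    th_vib: float
    ts: float
    win_size: int

    def __post_init__(self):
        if self.d < 1:
            raise ConfigError("minimal peak distance d must be >= 1")
        if self.h <= 0 or self.th_vib <= 0 or self.ts <= 0:
            raise ConfigError("H, th_vib and Ts must be positive")
        if self.win_size < 3:
            raise ConfigError("win_size must be >= 3 samples")


def profile_for(state: MotionState, fs: float, overrides: dict | None = None) -> StateProfile:
    """Build the per-state parameter bundle at sampling rate ``fs``.

    ``win_size`` is computed as ``round(ts * fs) - 1`` from the (possibly
    overridden) step period; any field may be overridden, including
    ``win_size`` itself.
    """
    if fs <= 0:
        raise ConfigError("fs must be positive")
    ov = dict(overrides or {})
    unknown = set(ov) - {"d", "h", "th_vib", "ts", "win_size"}
    if unknown:
        raise ConfigError(f"unknown profile override(s): {sorted(unknown)}")
    ts = float(ov.get("ts", DEFAULT_TS[state]))
    # round half-up, then subtract 1 (keeps the window just under one step)
    win_size = int(ov.get("win_size", int(np.floor(ts * fs + 0.5)) - 1))
    return StateProfile(
        state=state,
        d=int(ov.get("d", DEFAULT_D[state])),
        h=float(ov.get("h", DEFAULT_H[state])),
        th_vib=float(ov.get("th_vib", DEFAULT_TH_VIB[state])),
        ts=ts,
        win_size=win_size,
    )


def window_mean_magnitude(
    mag: MagnitudeSeries, window_s: float = DEFAULT_WINDOW_S
) -> tuple[np.ndarray, np.ndarray]:
    """Sliding window mean of the magnitude with 50% overlap.

    Returns ``(centers, means)``: the window centre times (s) and the mean
    magnitude (g) of each window. A series shorter than one window yields a
    single whole-series mean.
    """
    if window_s <= 0:
        raise ConfigError("window_s must be positive")
    win = int(round(window_s * mag.fs))
    if win < 2:
        raise ConfigError("window_s * fs must be >= 2 samples")
    n = len(mag)
    if n == 0:
        raise ConfigError("empty magnitude series")
    if n < win:
        return (np.array([0.5 * (mag.t[0] + mag.t[-1])]), np.array([float(np.mean(mag.acc))]))
    hop = max(1, win // 2)
    starts = np.arange(0, n - win + 1, hop)
    # np.add.reduceat sums win-sample blocks starting at each offset
    csum = np.concatenate([[0.0], np.cumsum(mag.acc)])
    means = (csum[starts + win] - csum[starts]) / win
    centers = mag.t[starts] + 0.5 * (win - 1) / mag.fs
    return centers, means


def classify_state(mean_mag: float, cfg: ClassifierConfig | None = None) -> MotionState:
    """Label a window mean: SLOW below M1, NORMAL in [M1, M2), FAST above."""
    cfg = cfg or ClassifierConfig()
    if mean_mag < 0:
        raise ConfigError("mean magnitude must be non-negative")
    if mean_mag < cfg.m1:
        return MotionState.SLOW
    if mean_mag < cfg.m2:
        return MotionState.NORMAL
    return MotionState.FAST


def states_per_sample(
    mag: MagnitudeSeries, cfg: ClassifierConfig | None = None
) -> np.ndarray:
    """Assign every sample the state of the nearest classification window.

    Returns an object array of :class:`MotionState`, one entry per sample.
    This is the granularity used by the full pipeline: a peak inherits the
    state of the window whose centre is closest to its time.
    """
    cfg = cfg or ClassifierConfig()
    centers, means = window_mean_magnitude(mag, cfg.window_s)
    labels = np.array([classify_state(m, cfg) for m in means], dtype=object)
    idx = np.searchsorted(centers, mag.t)
    idx = np.clip(idx, 1, len(centers) - 1) if len(centers) > 1 else np.zeros(len(mag), int)
    if len(centers) > 1:
        left = centers[idx - 1]
        right = centers[idx]
        idx = np.where(np.abs(mag.t - left) <= np.abs(right - mag.t), idx - 1, idx)
    return labels[idx]
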