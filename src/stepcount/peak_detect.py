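"""Phase 3: candidate peak detection and the four false-peak filters.

Candidate extrema must dominate their d-sample neighbourhoods (minimal peak
distance), then survive three independent predicates:

* minimal peak prominence — the intrinsic height of the peak above the
  higher of the two interval minima found by extending a horizontal line
  left/right until a strictly higher sample or the window edge is met;
* dynamic thresholding — the peak must exceed the mid-range
  (max + min) / 2 of its surrounding window by at least Th_D;
* vibration elimination — peaks whose amplitude stays within Th_vib of the
  1 g gravity baseline are shaking, not stepping.

All amplitudes are in g units; the windows are ``win_size`` samples centred
on the peak, derived from the state's mean step period.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .errors import ConfigError
from .preprocess import MagnitudeSeries
from .state_profile import MotionState, StateProfile

#: Fixed margin (g) a peak must clear above its window mid-range.
DEFAULT_TH_D = 0.15


@dataclass
class Peak:
    """A candidate step extremum and the filter evidence gathered about it."""

    index: int
    time: float
    amplitude: float
    prominence: float = float("nan")
    vib_eli: float = float("nan")
    state: MotionState | None = None
    flags: set = field(default_factory=set)


@dataclass(frozen=True)
class DynamicThresholdConfig:
    """Margin Th_D (g) and centred window length for dynamic thresholding."""

    th_d: float = DEFAULT_TH_D
    win_size: int = 24

    def __post_init__(self):
        if self.th_d <= 0:
            raise ConfigError("th_d must be positive")
        if self.win_size < 3:
            raise ConfigError("win_size must be >= 3")


def _window_bounds(index: int, win_size: int, n: int) -> tuple[int, int]:
    """Half-open [lo, hi) bounds of a win_size window centred on ``index``,
    clipped at the series edges."""
    lo = max(0, index - win_size // 2)
    hi = min(n, lo + win_size)
    lo = max(0, hi - win_size)
    return lo, hi


def candidate_peaks(mag: MagnitudeSeries, d: int) -> list[Peak]:
    """All interior samples that dominate d neighbours on each side.

    A sample qualifies when it is >= every sample within d positions on both
    sides (windows clipped at the recording edges; the two endpoints never
    qualify). Plateaus admit several equal qualifiers; within any d-sample
    span only the higher peak is kept, ties resolved to the earlier index.
    """
    if d < 1:
        raise ConfigError("d must be >= 1")
    acc = mag.acc
    n = len(acc)
    if n <= 2 * d:
        return []
    pad = np.concatenate([np.full(d, -np.inf), acc, np.full(d, -np.inf)])
    # trailing max over acc[j-d:j] and leading max over acc[j+1:j+d+1]
    left_max = sliding_window_view(pad[: n + d - 1], d).max(axis=1)
    right_max = sliding_window_view(pad[d + 1 :], d).max(axis=1)
    ok = (acc >= left_max) & (acc >= right_max)
    ok[0] = ok[-1] = False
    idx = np.flatnonzero(ok)

    kept: list[int] = []
    for j in idx:
        if kept and j - kept[-1] <= d:
            if acc[j] > acc[kept[-1]]:
                kept[-1] = j
        else:
            kept.append(int(j))
    return [Peak(index=j, time=float(mag.t[j]), amplitude=float(acc[j]), flags={"distance_ok"}) for j in kept]


def peak_prominence(mag: MagnitudeSeries, peak: Peak, window: tuple[int, int]) -> float:
    """Prominence of ``peak`` evaluated inside ``window`` = (lo, hi) inclusive.

    From the peak, walk left and right until a strictly higher sample or the
    window edge; the base on each side is the minimum of the traversed
    interval. Prominence is the peak amplitude minus the higher base. The
    window's global maximum reaches both edges and measures against the
    higher of the two edge-interval minima.
    """
    lo, hi = window
    acc = mag.acc
    j = peak.index
    if not (lo <= j <= hi):
        raise ConfigError("peak index outside prominence window")
    amp = acc[j]

    left = acc[lo:j][::-1]  # from j-1 leftwards
    higher = np.flatnonzero(left > amp)
    stop = higher[0] if len(higher) else len(left)
    left_min = left[:stop].min() if stop > 0 else amp

    right = acc[j + 1 : hi + 1]
    higher = np.flatnonzero(right > amp)
    stop = higher[0] if len(higher) else len(right)
    right_min = right[:stop].min() if stop > 0 else amp

    return float(amp - max(left_min, right_min))


def prominence_filter(mag: MagnitudeSeries, peaks: list[Peak], h: float, win_size: int) -> list[Peak]:
    """Keep peaks whose prominence (within a centred win_size window) >= H."""
    kept = []
    n = len(mag)
    for p in peaks:
        lo, hi = _window_bounds(p.index, win_size, n)
        p.prominence = peak_prominence(mag, p, (lo, hi - 1))
        if p.prominence >= h:
            p.flags.add("prominence_ok")
            kept.append(p)
    return kept


def dynamic_threshold_filter(
    mag: MagnitudeSeries, peaks: list[Peak], cfg: DynamicThresholdConfig
) -> list[Peak]:
    """Keep peaks clearing the window mid-range by the margin Th_D.

    For each peak, ``Aver_D = (max + min) / 2`` of the magnitude over a
    win_size-sample window centred on the peak (clipped at the edges); the
    peak survives iff ``Acc(peak) - Aver_D >= th_d``.
    """
    kept = []
    n = len(mag)
    for p in peaks:
        lo, hi = _window_bounds(p.index, cfg.win_size, n)
        w = mag.acc[lo:hi]
        aver_d = 0.5 * (w.max() + w.min())
        if p.amplitude - aver_d >= cfg.th_d:
            p.flags.add("dynamic_ok")
            kept.append(p)
    return kept


def vibration_filter(peaks: list[Peak], th_vib: float) -> list[Peak]:
    """Drop peaks fluctuating around the 1 g gravity baseline.

    ``Vib_Eli = amplitude - 1`` (g); a peak survives iff ``Vib_Eli >= th_vib``.
    """
    if th_vib <= 0:
        raise ConfigError("th_vib must be positive")
    kept = []
    for p in peaks:
        p.vib_eli = p.amplitude - 1.0
        if p.vib_eli >= th_vib:
            p.flags.add("vibration_ok")
            kept.append(p)
    return kept


def detect_peaks(
    mag: MagnitudeSeries,
    profile: StateProfile,
    cfg: DynamicThresholdConfig | None = None,
) -> list[Peak]:
    """Run the full Phase 3 chain for one state-homogeneous segment.

    Order: minimal peak distance -> minimal peak prominence -> dynamic
    thresholding -> vibration elimination. Each stage only removes peaks, so
    the surviving count is monotone non-increasing in every threshold.
    """
    if cfg is None:
        cfg = DynamicThresholdConfig(win_size=profile.win_size)
    peaks = candidate_peaks(mag, profile.d)
    peaks = prominence_filter(mag, peaks, profile.h, profile.win_size)
    peaks = dynamic_threshold_filter(mag, peaks, cfg)
    peaks = vibration_filter(peaks, profile.th_vib)
    for p in peaks:
        p.state = profile.state
    return peaks
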