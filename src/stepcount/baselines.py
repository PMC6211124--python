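"""Comparison methods: plain peak counting and cascade-validated counting.

Two reference pedometer algorithms used to contrast against the full
pipeline:

* ``peak_only`` — peak detection with a minimal peak distance and a fixed
  height threshold, nothing else. Over-counts on noisy signals and counts
  false walking wholesale.
* ``psc`` — peak detection followed by periodicity, similarity and a
  continuity rule, with *cascade elimination*: when a peak fails the
  similarity comparison, the confirmed peak it was compared against is
  discarded too. Robust to false walking but under-counts noisy true
  walking, because one false peak can take true peaks down with it.

The continuity rule ("no gap longer than twice the periodicity band inside
a bout; a longer gap restarts the bout") is a reconstruction: the method it
mimics is only summarised, not fully printed, in the literature this
package draws on. Both baselines consume the raw (unfiltered) magnitude:
the preprocessing filter is part of the proposed pipeline, not of these
references.
"""

from __future__ import annotations

from dataclasses import dataclass

from .errors import ConfigError
from .peak_detect import candidate_peaks
from .preprocess import MagnitudeSeries
from .step_validate import EvalResult, ValidationConfig, periodicity, similarity

#: Fixed height threshold (g) for the plain peak-detection baseline.
DEFAULT_MIN_HEIGHT = 1.1


@dataclass(frozen=True)
class BaselineResult:
    method: str  # "peak_only" | "psc"
    e: int
    eval: EvalResult | None = None


def count_peak_only(mag: MagnitudeSeries, d: int = 12, min_height: float = DEFAULT_MIN_HEIGHT) -> int:
    """Steps = peaks clearing a fixed height, under minimal peak distance."""
    if d < 1:
        raise ConfigError("d must be >= 1")
    return sum(1 for p in candidate_peaks(mag, d) if p.amplitude >= min_height)


def count_psc(
    mag: MagnitudeSeries,
    cfg: ValidationConfig | None = None,
    d: int = 12,
    min_height: float = DEFAULT_MIN_HEIGHT,
) -> int:
    """Periodicity + similarity + continuity counting with cascade removal.

    Peaks are the same candidates as :func:`count_peak_only`. A bout restarts
    after a gap > 2 * t_max (continuity). Within a bout, a peak must arrive
    within [t_min, t_max] of the *preceding candidate peak* (whether or not
    that one was kept — the step interval of consecutive detected peaks);
    its amplitude is then compared with the kept peak two back, and on
    failure *both* are removed. These two couplings — an interloper breaks
    its successor's interval, and a similarity failure takes the comparison
    partner down — are what make this method under-count noisy signals.
    """
    cfg = cfg or ValidationConfig()
    peaks = [p for p in candidate_peaks(mag, d) if p.amplitude >= min_height]
    kept = []  # kept peaks of the current bout
    count = 0
    prev = None  # previous *candidate*, kept or not: Eq-style periodicity
    for p in peaks:
        if prev is None or periodicity(prev, p, mag.fs) > 2 * cfg.t_max:
            kept = [p]  # continuity break: restart the bout
            count += 1
            prev = p
            continue
        gap = periodicity(prev, p, mag.fs)
        prev = p
        if not (cfg.t_min <= gap <= cfg.t_max):
            continue  # a rejected peak still breaks its successor's interval
        if len(kept) >= 2 and -similarity(kept[-2], p) > cfg.s_tol:
            kept.pop(-2)  # cascade: the comparison partner goes too
            count -= 1
            continue
        kept.append(p)
        count += 1
    return count
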