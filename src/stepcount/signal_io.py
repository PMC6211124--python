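"""Reading, writing and normalising accelerometer recordings.

Recordings are plain CSV files with one time column and three acceleration
columns. Internally everything is expressed in g units (multiples of standard
gravity) on a uniform sampling grid, so that a device at rest has a vector
magnitude of 1 g regardless of orientation.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import ConfigError, DataError, FormatError, UnitDetectionError

logger = logging.getLogger(__name__)

#: Standard gravity, used to convert m/s^2 recordings to g units.
STANDARD_GRAVITY = 9.80665

#: Default CSV column names (time, then the three acceleration axes).
DEFAULT_COLUMNS = {"t": "t", "x": "x", "y": "y", "z": "z"}

#: Median-magnitude bands used by unit auto-detection, in the raw units.
_G_BAND = (0.6, 1.6)
_SI_BAND = (6.0, 14.0)

#: Relative tolerance between the median sample interval and 1/fs.
_GRID_RTOL = 0.01


@dataclass(frozen=True)
class AccelSeries:
    """A tri-axial acceleration recording on a uniform time grid.

    Attributes
    ----------
    t : ndarray
        Sample times in seconds, strictly increasing, uniform to within 1%.
    ax, ay, az : ndarray
        Acceleration along the three device axes, in ``source_units``.
    fs : float
        Sampling rate in Hz.
    source_units : str
        ``"g"`` or ``"m_per_s2"``. After :func:`normalize_units` this is
        always ``"g"``.
    """

    t: np.ndarray
    ax: np.ndarray
    ay: np.ndarray
    az: np.ndarray
    fs: float
    source_units: str = "g"

    def __post_init__(self):
        t, ax, ay, az = (np.asarray(a, dtype=float) for a in (self.t, self.ax, self.ay, self.az))
        object.__setattr__(self, "t", t)
        object.__setattr__(self, "ax", ax)
        object.__setattr__(self, "ay", ay)
        object.__setattr__(self, "az", az)
        n = len(t)
        if not (len(ax) == len(ay) == len(az) == n):
            raise DataError("time and axis arrays must have equal length")
        if n == 0:
            return  # degenerate empty recording (e.g. zero-duration request)
        if n < 2:
            raise DataError("a recording needs at least 2 samples")
        dt = np.diff(t)
        if np.any(dt <= 0):
            raise DataError("time stamps must be strictly increasing")
        if self.fs <= 0:
            raise ConfigError("sampling rate must be positive")
        nominal = 1.0 / self.fs
        if abs(np.median(dt) - nominal) / nominal >= _GRID_RTOL:
            raise DataError(
                f"median sample interval {np.median(dt):.6g}s deviates >1% from 1/fs={nominal:.6g}s"
            )
        if self.source_units not in ("g", "m_per_s2"):
            raise ConfigError(f"unknown units {self.source_units!r}")

    def __len__(self) -> int:
        return len(self.t)

    @property
    def duration(self) -> float:
        return float(self.t[-1] - self.t[0]) if len(self) else 0.0


@dataclass(frozen=True)
class GroundTruth:
    """Reference step annotation: a count and (optionally) the step times."""

    true_step_count: int
    step_times: np.ndarray | None = None

    def __post_init__(self):
        if self.true_step_count < 0:
            raise DataError("true step count must be non-negative")
        if self.step_times is not None:
            st = np.asarray(self.step_times, dtype=float)
            object.__setattr__(self, "step_times", st)
            if len(st) != self.true_step_count:
                raise DataError("step_times length must equal true_step_count")
            if len(st) > 1 and np.any(np.diff(st) <= 0):
                raise DataError("step_times must be strictly increasing")


def vector_magnitude(series: AccelSeries) -> np.ndarray:
    """Euclidean norm of the three axes, in the series' own units."""
    return np.sqrt(series.ax**2 + series.ay**2 + series.az**2)


def detect_units(series: AccelSeries) -> str:
    """Infer whether a recording is in g or m/s^2 from its resting magnitude.

    A still (or mostly-still) accelerometer reads gravity: the median vector
    magnitude is ~1 in g units and ~9.8 in m/s^2. Walking raises the median
    a little, hence the generous bands.
    """
    if len(series) < series.fs:
        raise DataError("need at least 1 s of data to detect units")
    med = float(np.median(vector_magnitude(series)))
    if _SI_BAND[0] <= med <= _SI_BAND[1]:
        return "m_per_s2"
    if _G_BAND[0] <= med <= _G_BAND[1]:
        return "g"
    raise UnitDetectionError(
        f"median magnitude {med:.3g} matches neither g nor m/s^2; pass units explicitly"
    )


def normalize_units(series: AccelSeries, units: str | None = None) -> AccelSeries:
    """Return the series in g units, converting from m/s^2 if needed.

    Idempotent: a series already in g units is returned unchanged (same
    values, ``source_units == "g"``).
    """
    units = units or series.source_units
    if units == "g":
        if series.source_units == "g":
            return series
        return replace(series, source_units="g")
    if units == "m_per_s2":
        return AccelSeries(
            t=series.t,
            ax=series.ax / STANDARD_GRAVITY,
            ay=series.ay / STANDARD_GRAVITY,
            az=series.az / STANDARD_GRAVITY,
            fs=series.fs,
            source_units="g",
        )
    raise ConfigError(f"unknown units {units!r}")


def read_accel_csv(
    path,
    column_map: dict | None = None,
    fs_hint: float | None = None,
    units: str | None = None,
) -> AccelSeries:
    """Read a CSV recording and return an :class:`AccelSeries` in g units.

    Parameters
    ----------
    path : str or Path
        CSV file with a header row.
    column_map : dict, optional
        Maps the logical names ``t, x, y, z`` to the file's column names.
        The time entry may be omitted when ``fs_hint`` is given.
    fs_hint : float, optional
        Sampling rate in Hz; required when the file has no time column,
        otherwise used only as a cross-check.
    units : {"g", "m_per_s2", "auto"}, optional
        Units of the acceleration columns. Default auto-detects from the
        median magnitude.

    Irregular time stamps (median-interval deviation > 1%) are resampled to
    the declared rate by linear interpolation, with a warning when more than
    5% of intervals are gaps.
    """
    cmap = dict(DEFAULT_COLUMNS)
    cmap.update(column_map or {})
    try:
        df = pd.read_csv(path)
    except (OSError, pd.errors.ParserError, pd.errors.EmptyDataError) as exc:
        raise FormatError(f"cannot parse {path}: {exc}") from exc

    missing = [cmap[k] for k in ("x", "y", "z") if cmap[k] not in df.columns]
    if missing:
        raise FormatError(f"missing acceleration column(s) {missing} in {path}")
    ax, ay, az = (df[cmap[k]].to_numpy(dtype=float) for k in ("x", "y", "z"))

    tcol = cmap.get("t")
    if tcol is not None and tcol in df.columns:
        t = df[tcol].to_numpy(dtype=float)
        dt = np.diff(t)
        if np.any(dt <= 0):
            raise DataError(f"time column {tcol!r} is not strictly increasing")
        med_dt = float(np.median(dt))
        fs = fs_hint if fs_hint else 1.0 / med_dt
        nominal = 1.0 / fs
        if np.abs(med_dt - nominal) / nominal >= _GRID_RTOL or np.any(
            np.abs(dt - nominal) / nominal >= _GRID_RTOL
        ):
            gap_ratio = float(np.mean(dt > 1.5 * nominal))
            if gap_ratio > 0.05:
                warnings.warn(
                    f"{gap_ratio:.0%} of sample intervals are gaps; "
                    "resampled signal may be unreliable",
                    stacklevel=2,
                )
            logger.info("irregular time stamps in %s: resampling to %.6g Hz", path, fs)
            t_new = t[0] + np.arange(int(np.floor((t[-1] - t[0]) * fs)) + 1) / fs
            ax, ay, az = (np.interp(t_new, t, a) for a in (ax, ay, az))
            t = t_new
    else:
        if not fs_hint:
            raise ConfigError(
                f"no time column {tcol!r} in {path} and no fs_hint given"
            )
        fs = float(fs_hint)
        t = np.arange(len(ax)) / fs

    series = AccelSeries(t=t, ax=ax, ay=ay, az=az, fs=fs, source_units="g")
    if units in (None, "auto"):
        units = detect_units(series)
    return normalize_units(replace(series, source_units=units), units)


def write_steps(steps, path) -> None:
    """Write confirmed steps to CSV (header mandatory, one row per step).

    Columns: ``step_index, time_s, state, peak_amplitude_g``.
    """
    rows = [
        {
            "step_index": i,
            "time_s": s.time,
            "state": s.state.name.lower(),
            "peak_amplitude_g": s.amplitude,
        }
        for i, s in enumerate(steps)
    ]
    pd.DataFrame(rows, columns=["step_index", "time_s", "state", "peak_amplitude_g"]).to_csv(
        path, index=False
    )


def read_steps(path) -> pd.DataFrame:
    """Read back a step CSV written by :func:`write_steps`."""
    df = pd.read_csv(path)
    expected = ["step_index", "time_s", "state", "peak_amplitude_g"]
    if list(df.columns) != expected:
        raise FormatError(f"step file {path} must have columns {expected}")
    return df


def read_ground_truth_csv(path) -> GroundTruth:
    """Read a ground-truth annotation: a single ``time_s`` column of step times."""
    df = pd.read_csv(path)
    if "time_s" not in df.columns:
        raise FormatError(f"ground-truth file {path} needs a time_s column")
    times = df["time_s"].to_numpy(dtype=float)
    return GroundTruth(true_step_count=len(times), step_times=times)
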