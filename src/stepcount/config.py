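"""YAML configuration for the CLI and for batch runs.

Schema (all keys optional; unknown keys are rejected)::

    io:
      time_col: t
      x_col: x
      y_col: y
      z_col: z
      units: auto        # auto | g | m_per_s2
      fs: null           # Hz, required when there is no time column
    preprocess:
      cutoff_hz: 3.0
    states:
      m1: 1.16           # g, slow/normal boundary
      m2: 1.22           # g, normal/fast boundary
      window_s: 2.0
      slow:   {d: 14, h: 0.20, th_vib: 0.08, ts: 0.635}
      normal: {d: 12, h: 0.25, th_vib: 0.10, ts: 0.507}
      fast:   {d: 10, h: 0.35, th_vib: 0.15, ts: 0.469}
    peaks:
      th_d: 0.15
    validate:
      t_min: 0.35
      t_max: 0.80
      s_tol: 0.3
"""

from __future__ import annotations

from dataclasses import dataclass, field

import yaml

from .errors import ConfigError
from .state_profile import ClassifierConfig, MotionState
from .step_validate import PipelineConfig, ValidationConfig

_SECTIONS = {"io", "preprocess", "states", "peaks", "validate"}


@dataclass(frozen=True)
class IOConfig:
    column_map: dict = field(
        default_factory=lambda: {"t": "t", "x": "x", "y": "y", "z": "z"}
    )
    units: str | None = None  # None/auto -> auto-detect
    fs: float | None = None


def _pick(d: dict, key: str, default):
    return d[key] if key in d else default


def load_config(path=None, data: dict | None = None) -> tuple[IOConfig, PipelineConfig]:
    """Load a YAML config file (or an already-parsed dict) into config objects."""
    if data is None:
        if path is None:
            return IOConfig(), PipelineConfig()
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise ConfigError("config root must be a mapping")
    unknown = set(data) - _SECTIONS
    if unknown:
        raise ConfigError(f"unknown config section(s): {sorted(unknown)}")

    io = data.get("io", {}) or {}
    cmap = {
        "t": _pick(io, "time_col", "t"),
        "x": _pick(io, "x_col", "x"),
        "y": _pick(io, "y_col", "y"),
        "z": _pick(io, "z_col", "z"),
    }
    units = _pick(io, "units", None)
    io_cfg = IOConfig(
        column_map=cmap,
        units=None if units in (None, "auto") else units,
        fs=_pick(io, "fs", None),
    )

    states = data.get("states", {}) or {}
    classifier = ClassifierConfig(
        m1=_pick(states, "m1", ClassifierConfig().m1),
        m2=_pick(states, "m2", ClassifierConfig().m2),
        window_s=_pick(states, "window_s", ClassifierConfig().window_s),
    )
    overrides = {}
    for st in MotionState:
        sub = states.get(st.value)
        if sub:
            bad = set(sub) - {"d", "h", "th_vib", "ts", "win_size"}
            if bad:
                raise ConfigError(f"unknown key(s) {sorted(bad)} in states.{st.value}")
            overrides[st] = dict(sub)

    validate = data.get("validate", {}) or {}
    vcfg = ValidationConfig(
        t_min=_pick(validate, "t_min", ValidationConfig().t_min),
        t_max=_pick(validate, "t_max", ValidationConfig().t_max),
        s_tol=_pick(validate, "s_tol", ValidationConfig().s_tol),
    )

    pipeline = PipelineConfig(
        cutoff_hz=_pick(data.get("preprocess", {}) or {}, "cutoff_hz", 3.0),
        classifier=classifier,
        th_d=_pick(data.get("peaks", {}) or {}, "th_d", 0.15),
        validation=vcfg,
        profile_overrides=overrides,
    )
    return io_cfg, pipeline
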