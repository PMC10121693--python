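"""Plain-text configuration: one ``key: value`` line per model symbol.

A config file carries the dimensional parameters plus the grid/stepping
controls.  Unknown keys are an error (typos must not silently fall back to
defaults).  Parsing is YAML-compatible, so the files also read naturally as
YAML.
"""

from __future__ import annotations

from dataclasses import fields

import yaml

from .parameters import DimensionalParameters

__all__ = ["load_config", "dump_config", "CONTROL_KEYS"]

PARAM_KEYS = tuple(f.name for f in fields(DimensionalParameters))
CONTROL_KEYS = ("h", "dt", "t_max", "stepper", "snapshot_times",
                "series_interval", "upwind")
_STR_KEYS = {"stepper"}
_LIST_KEYS = {"snapshot_times"}
_BOOL_KEYS = {"upwind"}


def load_config(path) -> tuple[DimensionalParameters, dict]:
    """Read a config file; returns ``(params, controls)``.

    Keys from the dimensional parameter set override the defaults; control
    keys (``h, dt, t_max, stepper, snapshot_times, series_interval,
    upwind``) are collected into the controls dict.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ValueError(f"{path}: expected key: value lines")
    params_kw: dict = {}
    controls: dict = {}
    for key, value in raw.items():
        if key in PARAM_KEYS:
            params_kw[key] = float(value)
        elif key in CONTROL_KEYS:
            if key in _STR_KEYS:
                controls[key] = str(value)
            elif key in _BOOL_KEYS:
                controls[key] = bool(value)
            elif key in _LIST_KEYS:
                if isinstance(value, str):
                    value = [v for v in value.replace(",", " ").split() if v]
                controls[key] = tuple(float(v) for v in value)
            else:
                controls[key] = float(value)
        else:
            raise ValueError(f"{path}: unknown configuration key {key!r}")
    return DimensionalParameters(**params_kw), controls


def dump_config(params: DimensionalParameters, controls: dict | None = None,
                path=None) -> str:
    """Serialize a parameter set (and controls) back to config text."""
    lines = [f"{k}: {v!r}" for k, v in params.as_dict().items()]
    for k, v in (controls or {}).items():
        if k not in CONTROL_KEYS:
            raise ValueError(f"unknown control key {k!r}")
        if isinstance(v, tuple):
            v = list(v)
        lines.append(f"{k}: {v!r}")
    text = "\n".join(lines) + "\n"
    if path is not None:
        with open(path, "w") as fh:
            fh.write(text)
    return text
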