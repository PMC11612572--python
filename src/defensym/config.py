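"""Configuration loading and validation.

Configs are flat key-value files (YAML-compatible).  Keys may use either the
canonical field names of :class:`~defensym.params.SimulationParams` or the
conventional short parameter names (``hosts``, ``parasitoids``, ``p``,
``S_un``, ``lambda_un``, ``S_p``, ``lambda_p``, ``R``), plus
``grid_width``/``grid_height``.  Aggregation ``a`` and initial level ``p``
also accept percentage strings ("4%" -> 0.04).  Unknown keys are rejected.
"""

from __future__ import annotations

from pathlib import Path

import yaml

from .landscape import GridSpec
from .params import SimulationParams

__all__ = ["ConfigError", "load_config", "config_to_dict"]

# external name -> SimulationParams field
ALIASES = {
    "hosts": "n_hosts",
    "parasitoids": "n_parasitoids",
    "p": "p0",
    "S_un": "s_un",
    "Sun": "s_un",
    "S_p": "s_p",
    "Sp": "s_p",
    "R": "r",
    "lambda_p": "lambda_p",
    "lambda_un": "lambda_un",
}

_PERCENT_OK = {"a", "p0", "c", "h", "r"}
_BOOL_FIELDS = {
    "transmission_enabled",
    "sticky_target",
    "deterministic_rounding",
    "paired",
}
_INT_FIELDS = {
    "n_hosts",
    "n_parasitoids",
    "n_generations",
    "n_replicates",
    "seed",
}


class ConfigError(ValueError):
    """A configuration key or value failed validation."""


def _coerce(field: str, value):
    if isinstance(value, str) and value.strip().endswith("%"):
        if field not in _PERCENT_OK:
            raise ConfigError(f"{field} does not accept percentage values")
        try:
            return float(value.strip().rstrip("%")) / 100.0
        except ValueError as exc:
            raise ConfigError(f"{field}: cannot parse percentage {value!r}") from exc
    if field in _BOOL_FIELDS:
        if isinstance(value, bool):
            return value
        if isinstance(value, str):
            lowered = value.strip().lower()
            if lowered in {"true", "yes", "1", "on"}:
                return True
            if lowered in {"false", "no", "0", "off"}:
                return False
        raise ConfigError(f"{field}: expected a boolean, got {value!r}")
    if field in _INT_FIELDS:
        try:
            as_float = float(value)
        except (TypeError, ValueError) as exc:
            raise ConfigError(f"{field}: expected an integer, got {value!r}") from exc
        if as_float != int(as_float):
            raise ConfigError(f"{field}: expected an integer, got {value!r}")
        return int(as_float)
    if field == "kappa" and value is None:
        return None
    try:
        return float(value)
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"{field}: expected a number, got {value!r}") from exc


def load_config(
    path: str | Path | None = None, overrides: dict | None = None
) -> SimulationParams:
    """Build a validated :class:`SimulationParams` from a file and overrides.

    File values are read first; ``overrides`` (e.g. CLI flags) take
    precedence.  Defaults are the fixed study conditions.  Raises
    :class:`ConfigError` naming the offending key and permitted range.
    """
    raw: dict = {}
    if path is not None:
        text = Path(path).read_text()
        loaded = yaml.safe_load(text) or {}
        if not isinstance(loaded, dict):
            raise ConfigError(f"config file {path} is not a flat key-value mapping")
        raw.update(loaded)
    if overrides:
        raw.update({k: v for k, v in overrides.items() if v is not None})

    known = set(SimulationParams.field_names()) - {"grid"}
    known |= {"grid_width", "grid_height"}
    fields: dict = {}
    grid_kw: dict = {}
    for key, value in raw.items():
        field = ALIASES.get(key, key)
        if field not in known:
            raise ConfigError(
                f"unknown configuration key {key!r}; known keys: "
                + ", ".join(sorted(known | set(ALIASES)))
            )
        if field in ("grid_width", "grid_height"):
            grid_kw[field.removeprefix("grid_")] = int(value)
        else:
            fields[field] = _coerce(field, value)
    if grid_kw:
        fields["grid"] = GridSpec(
            width=grid_kw.get("width", 500), height=grid_kw.get("height", 500)
        )
    try:
        return SimulationParams(**fields)
    except ValueError as exc:
        raise ConfigError(str(exc)) from exc


def config_to_dict(params: SimulationParams) -> dict:
    """Round-trippable flat representation of a parameter set."""
    return params.to_dict()
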