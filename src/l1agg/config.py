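"""Structured-text configuration: INI-style sections with key = value.

Layering: built-in defaults (the reference parameter table) -> config
file -> programmatic overrides.  The bundled ``data/default.ini``
reproduces the defaults exactly.
"""

from __future__ import annotations

import configparser
import hashlib
import json
import warnings
from dataclasses import asdict, fields
from importlib import resources
from pathlib import Path

from .model import ModelParameters, SlowdownSchedule
from .scenarios import ScenarioConfig

__all__ = ["parse_config", "default_config_path", "parameter_hash",
           "ConfigurationError"]

_MODEL_FIELDS = {f.name: f.type for f in fields(ModelParameters)}
_SCENARIO_FIELDS = {f.name: f.type for f in fields(ScenarioConfig)}
_SLOWDOWN_FIELDS = {f.name: f.type for f in fields(SlowdownSchedule)}


class ConfigurationError(ValueError):
    """Invalid or unknown configuration content, with an itemized message."""


def default_config_path() -> Path:
    return Path(str(resources.files("l1agg").joinpath("data/default.ini")))


def _coerce(raw: str, target_example) -> object:
    if isinstance(target_example, bool):
        lo = raw.strip().lower()
        if lo in ("true", "yes", "on", "1"):
            return True
        if lo in ("false", "no", "off", "0"):
            return False
        raise ValueError(f"expected a boolean, got {raw!r}")
    if isinstance(target_example, int):
        return int(raw)
    if isinstance(target_example, float):
        return float(raw)
    if isinstance(target_example, tuple):
        return tuple(float(x) for x in raw.split(",") if x.strip())
    return raw


def parse_config(path: str | Path | None = None, **overrides
                 ) -> tuple[ScenarioConfig, ModelParameters]:
    """Parse a config file into (ScenarioConfig, ModelParameters).

    Recognized sections are [model], [scenario], and [slowdown]; unknown
    sections or keys are rejected.  An empty or missing file yields the
    built-in defaults.
    """
    cp = configparser.ConfigParser()
    cp.optionxform = str                       # keys are case-sensitive (D_a vs d_a)
    if path is not None:
        path = Path(path)
        if not path.exists():
            raise ConfigurationError(f"config file not found: {path}")
        cp.read(path)

    problems: list[str] = []
    model_defaults = ModelParameters()
    scenario_defaults = ScenarioConfig()
    slowdown_defaults = SlowdownSchedule()

    model_kwargs: dict = {}
    scenario_kwargs: dict = {}
    slowdown_kwargs: dict = {}
    for section in cp.sections():
        if section == "model":
            sink, known, defaults = model_kwargs, _MODEL_FIELDS, model_defaults
        elif section == "scenario":
            sink, known, defaults = scenario_kwargs, _SCENARIO_FIELDS, scenario_defaults
        elif section == "slowdown":
            sink, known, defaults = slowdown_kwargs, _SLOWDOWN_FIELDS, slowdown_defaults
        else:
            problems.append(f"unknown section [{section}]")
            continue
        for key, raw in cp.items(section):
            if key not in known or key == "params":
                problems.append(f"unknown key {key!r} in [{section}]")
                continue
            try:
                sink[key] = _coerce(raw, getattr(defaults, key))
            except ValueError as e:
                problems.append(f"bad value for {key!r} in [{section}]: {e}")

    if problems:
        raise ConfigurationError("; ".join(problems))

    model_kwargs.update({k: v for k, v in overrides.items() if k in _MODEL_FIELDS})
    scenario_kwargs.update({k: v for k, v in overrides.items()
                            if k in _SCENARIO_FIELDS and k != "params"})
    try:
        params = ModelParameters(**model_kwargs)
    except ValueError as e:
        raise ConfigurationError(str(e)) from e
    if params.repellent_enabled and params.beta_r > 0:
        warnings.warn("beta_r > 0 with repellent enabled: a repellent is "
                      "defined by negative beta", stacklevel=2)
    if slowdown_kwargs:
        scenario_kwargs.setdefault("variant", "slowdown")
        if "tau" in slowdown_kwargs:
            scenario_kwargs["tau"] = slowdown_kwargs["tau"]
    try:
        scenario = ScenarioConfig(params=params, **scenario_kwargs)
    except ValueError as e:
        raise ConfigurationError(str(e)) from e
    return scenario, params


def parameter_hash(params: ModelParameters) -> str:
    """Stable short hash of the full parameter set, for provenance checks."""
    payload = json.dumps(asdict(params), sort_keys=True)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]
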