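"""Configuration loading (YAML or JSON) with validated defaults.

A scenario config names or spells out each pipeline component; absent
keys fall back to the reference study design: two 30-day seasons, five
recorded minutes per day, 100 sites, false alarms at 48/h, the HH
dynamics case with a low call rate and the good classifier, 1-day
aggregation at a 0.95 threshold with 5% confirmation.
"""

from __future__ import annotations

from pathlib import Path

import yaml

from .aggregation import AggregationConfig
from .dynamics import DynamicsParams
from .experiments import DYNAMICS_SCENARIOS, ScenarioConfig, reference_scenario_grid
from .soundscape import BAD_CLASSIFIER, GOOD_CLASSIFIER, ClassifierSpec, RecordingSchedule

__all__ = ["ConfigError", "load_config"]

_CLASSIFIERS = {"good": GOOD_CLASSIFIER, "bad": BAD_CLASSIFIER}


class ConfigError(ValueError):
    """Raised for unparseable, unknown or invalid configuration values."""


def _build(cls, data: dict, what: str):
    try:
        return cls(**data)
    except TypeError as exc:
        raise ConfigError(f"invalid {what} config: {exc}") from None
    except ValueError as exc:
        raise ConfigError(f"invalid {what} config: {exc}") from None


def _parse_dynamics(value) -> DynamicsParams:
    if isinstance(value, str):
        try:
            return DYNAMICS_SCENARIOS[value.upper()]
        except KeyError:
            raise ConfigError(
                f"unknown dynamics scenario {value!r}; "
                f"expected one of {sorted(DYNAMICS_SCENARIOS)}"
            ) from None
    if isinstance(value, dict):
        return _build(DynamicsParams, value, "dynamics")
    raise ConfigError(f"dynamics must be a scenario name or mapping, got {value!r}")


def _parse_classifier(value) -> ClassifierSpec:
    if isinstance(value, str):
        try:
            return _CLASSIFIERS[value.lower()]
        except KeyError:
            raise ConfigError(
                f"unknown classifier {value!r}; expected 'good' or 'bad'"
            ) from None
    if isinstance(value, dict):
        return _build(ClassifierSpec, value, "classifier")
    raise ConfigError(f"classifier must be a name or mapping, got {value!r}")


_SCENARIO_KEYS = {
    "dynamics",
    "lambda_c",
    "lambda_f",
    "classifier",
    "schedule",
    "aggregation",
    "n_sites",
    "seed",
}
_GRID_KEYS = {
    "base_seed",
    "n_sites",
    "dynamics",
    "call_rates",
    "classifiers",
    "aggregation_days",
    "thresholds",
    "confirm_props",
}


def _parse_scenario(data: dict) -> ScenarioConfig:
    unknown = set(data) - _SCENARIO_KEYS
    if unknown:
        raise ConfigError(f"unknown config keys: {sorted(unknown)}")
    return _build(
        ScenarioConfig,
        {
            "dynamics": _parse_dynamics(data.get("dynamics", "HH")),
            "lambda_c": float(data.get("lambda_c", 20.0)),
            "lambda_f": float(data.get("lambda_f", 48.0)),
            "classifier": _parse_classifier(data.get("classifier", "good")),
            "schedule": _build(
                RecordingSchedule, data.get("schedule", {}) or {}, "schedule"
            ),
            "agg": _build(
                AggregationConfig, data.get("aggregation", {}) or {}, "aggregation"
            ),
            "n_sites": int(data.get("n_sites", 100)),
            "seed": int(data.get("seed", 0)),
        },
        "scenario",
    )


def _parse_grid(data: dict) -> list[ScenarioConfig]:
    unknown = set(data) - _GRID_KEYS
    if unknown:
        raise ConfigError(f"unknown grid keys: {sorted(unknown)}")
    kwargs: dict = {}
    if "dynamics" in data:
        kwargs["dynamics_labels"] = tuple(str(d).upper() for d in data["dynamics"])
    if "call_rates" in data:
        kwargs["call_rates"] = tuple(float(v) for v in data["call_rates"])
    if "classifiers" in data:
        kwargs["classifiers"] = tuple(
            _parse_classifier(v) for v in data["classifiers"]
        )
    if "aggregation_days" in data:
        kwargs["aggregation_days"] = tuple(int(v) for v in data["aggregation_days"])
    if "thresholds" in data:
        kwargs["thresholds"] = tuple(float(v) for v in data["thresholds"])
    if "confirm_props" in data:
        kwargs["confirm_props"] = tuple(float(v) for v in data["confirm_props"])
    try:
        return reference_scenario_grid(
            base_seed=int(data.get("base_seed", 0)),
            n_sites=int(data.get("n_sites", 100)),
            **kwargs,
        )
    except (KeyError, ValueError) as exc:
        raise ConfigError(f"invalid grid config: {exc}") from None


def load_config(path: str | Path) -> ScenarioConfig | list[ScenarioConfig]:
    """Read a YAML/JSON config file.

    A mapping with a top-level ``grid`` key expands to a list of
    scenarios (the full factorial cross of the listed factor levels);
    anything else — including an empty file — is a single scenario with
    defaults filled in.
    """
    text = Path(path).read_text()
    try:
        data = yaml.safe_load(text)
    except yaml.YAMLError as exc:
        raise ConfigError(f"cannot parse {path}: {exc}") from None
    if data is None:
        data = {}
    if not isinstance(data, dict):
        raise ConfigError(f"config root must be a mapping, got {type(data).__name__}")
    if "grid" in data:
        grid = data["grid"]
        if grid is True or grid is None:
            grid = {}
        if not isinstance(grid, dict):
            raise ConfigError("'grid' must be a mapping of factor levels")
        extra = set(data) - {"grid"}
        if extra:
            raise ConfigError(f"unexpected keys next to 'grid': {sorted(extra)}")
        return _parse_grid(grid)
    return _parse_scenario(data)
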