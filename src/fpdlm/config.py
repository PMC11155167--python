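"""Run configuration: validated parameter sets for the CLI commands.

Configs load from YAML or JSON, reject unknown keys with field-level
messages, and round-trip exactly (config -> file -> config).  Explicit
command-line flags take precedence over file values.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Literal

import yaml
from pydantic import BaseModel, ConfigDict, Field, ValidationError

__all__ = [
    "SimulateStudyConfig",
    "GenCohortConfig",
    "FitConfig",
    "parse_config",
    "ConfigError",
]


class ConfigError(ValueError):
    """Invalid run configuration (schema violation, bad value, unknown key)."""


class _StrictModel(BaseModel):
    model_config = ConfigDict(extra="forbid", validate_assignment=True)


class SimulateStudyConfig(_StrictModel):
    """Parameters of the simulation study (`simulate-study`)."""

    scenario: Literal[1, 2, 3] = 1
    gamma: float = Field(0.975, ge=0.0, lt=1.0)
    n: int = Field(10000, ge=100)
    reps: int = Field(1000, ge=2)
    models: list[Literal["single", "multi", "dlm"]] = ["single", "multi", "dlm"]
    seed: int = 0
    out_dir: str = "study-out"


class GenCohortConfig(_StrictModel):
    """Parameters of the synthetic three-wave cohort (`gen-cohort`)."""

    n: int = Field(10000, ge=1)
    seed: int = 0
    effect_log_or: float = 0.06765864847381804  # log(1.07)
    effect_window: tuple[float, float] = (30.0, 36.0)
    latent_corr: float = Field(0.975, ge=0.0, lt=1.0)
    outcome_prevalence: float = Field(0.17, gt=0.0, lt=1.0)
    out: str = "cohort.csv"
    truth_out: str | None = None  # default: out with .truth.json suffix


class FitConfig(_StrictModel):
    """Parameters of a cohort analysis (`fit`)."""

    cohort: str
    model: Literal["single", "multi", "dlm"] = "dlm"
    grid_min: float | None = Field(None, gt=0.0)
    grid_max: float | None = Field(None, gt=0.0)
    alpha: float = Field(0.05, gt=0.0, le=1.0)
    outcome_age_months: float = 36.0  # lag -> age translation for window reports
    out: str = "effects.csv"


_COMMANDS = {
    "simulate-study": SimulateStudyConfig,
    "gen-cohort": GenCohortConfig,
    "fit": FitConfig,
}


def parse_config(
    command: str,
    path: str | Path | None = None,
    overrides: dict | None = None,
):
    """Build a validated config for ``command``.

    File values (YAML or JSON) are applied first, then ``overrides``
    (typically explicit CLI flags).  Unknown keys and out-of-domain
    values raise :class:`ConfigError` naming the offending fields.
    """
    if command not in _COMMANDS:
        raise ConfigError(f"unknown command {command!r}; expected one of {sorted(_COMMANDS)}")
    data: dict = {}
    if path is not None:
        text = Path(path).read_text()
        loaded = yaml.safe_load(text) if not str(path).endswith(".json") else json.loads(text)
        if loaded is None:
            loaded = {}
        if not isinstance(loaded, dict):
            raise ConfigError(f"config file {path} must contain a mapping")
        data.update(loaded)
    for key, val in (overrides or {}).items():
        if val is not None:
            data[key] = val
    try:
        return _COMMANDS[command](**data)
    except ValidationError as err:
        msgs = "; ".join(
            f"{'.'.join(str(loc) for loc in e['loc']) or '(root)'}: {e['msg']}"
            for e in err.errors()
        )
        raise ConfigError(f"invalid {command} config: {msgs}") from err


def dump_config(cfg: _StrictModel, path: str | Path) -> None:
    """Serialize a config to YAML (or JSON if the path ends in .json)."""
    payload = cfg.model_dump(mode="json")
    path = Path(path)
    if path.suffix == ".json":
        path.write_text(json.dumps(payload, indent=2) + "\n")
    else:
        path.write_text(yaml.safe_dump(payload, sort_keys=False))
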