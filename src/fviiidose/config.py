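"""Study configuration: YAML loading, validation and hashing.

A study is fully described by a :class:`StudyConfig`: the virtual
population recipe, the population-PK constants, the regimen axes
(schedules × metrics × baselines), the dose grid, the safety criteria
and a master seed.  Every field has a default taken from the study
conditions, so an empty YAML file is a complete, runnable configuration.
Validation happens before any computation and reports all offending
keys at once.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml

from .dose_search import DoseGrid, default_dose_grid
from .pk_model import PKModelSpec
from .population import HeightDistribution, PopulationSpec
from .regimen import SCHEDULES
from .weight_metrics import METRIC_NAMES

__all__ = ["ConfigError", "StudyConfig", "load_config", "save_config", "config_hash"]


class ConfigError(ValueError):
    """Raised when a configuration fails schema validation."""


@dataclass(frozen=True)
class StudyConfig:
    """Complete, validated description of one titration study."""

    population: PopulationSpec = field(default_factory=PopulationSpec)
    pk: PKModelSpec = field(default_factory=PKModelSpec)
    schedules: tuple[str, ...] = ("q48h", "mwf")
    metrics: tuple[str, ...] = METRIC_NAMES
    baselines: tuple[float, ...] = (0.5, 0.0)
    q48h_criterion: float = 0.95
    mwf_criterion: float = 0.90
    grid: DoseGrid = field(default_factory=default_dose_grid)
    master_seed: int = 1234
    out_dir: str = "study_out"
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        bad = []
        if any(s not in SCHEDULES for s in self.schedules) or not self.schedules:
            bad.append("schedules")
        if any(m not in METRIC_NAMES for m in self.metrics) or not self.metrics:
            bad.append("metrics")
        if any(b < 0 for b in self.baselines) or not self.baselines:
            bad.append("baselines")
        if not 0.0 <= self.q48h_criterion <= 1.0:
            bad.append("q48h_criterion")
        if not 0.0 <= self.mwf_criterion <= 1.0:
            bad.append("mwf_criterion")
        if self.master_seed < 0:
            bad.append("master_seed")
        if bad:
            raise ConfigError(f"invalid configuration values for: {', '.join(bad)}")


def _to_dict(config: StudyConfig) -> dict:
    d = {
        "population": {
            "n_per_group": config.population.n_per_group,
            "bmi_normal_range": list(config.population.bmi_normal_range),
            "bmi_high_range": list(config.population.bmi_high_range),
            "height": asdict(config.population.height),
            "rng_seed": config.population.rng_seed,
        },
        "pk": asdict(config.pk),
        "schedules": list(config.schedules),
        "metrics": list(config.metrics),
        "baselines": list(config.baselines),
        "q48h_criterion": config.q48h_criterion,
        "mwf_criterion": config.mwf_criterion,
        "grid": {"segments": [list(s) for s in config.grid.segments]},
        "master_seed": config.master_seed,
        "out_dir": config.out_dir,
        "log_level": config.log_level,
    }
    return d


def _check_keys(given: dict, allowed: set[str], context: str) -> None:
    unknown = set(given) - allowed
    if unknown:
        raise ConfigError(
            f"unknown configuration keys in {context}: {', '.join(sorted(unknown))}"
        )


def _from_dict(raw: dict) -> StudyConfig:
    defaults = _to_dict(StudyConfig())
    _check_keys(raw, set(defaults), "top level")

    pop_raw = dict(raw.get("population") or {})
    _check_keys(pop_raw, set(defaults["population"]), "population")
    height_raw = dict(pop_raw.pop("height", None) or {})
    _check_keys(height_raw, set(defaults["population"]["height"]), "population.height")
    try:
        height = HeightDistribution(**{**defaults["population"]["height"], **height_raw})
        pop_kwargs = {
            k: v for k, v in {**defaults["population"], **pop_raw}.items() if k != "height"
        }
        for key in ("bmi_normal_range", "bmi_high_range"):
            pop_kwargs[key] = tuple(pop_kwargs[key])
        population = PopulationSpec(height=height, **pop_kwargs)

        pk_raw = dict(raw.get("pk") or {})
        _check_keys(pk_raw, set(defaults["pk"]), "pk")
        pk = PKModelSpec(**{**defaults["pk"], **pk_raw})

        grid_raw = dict(raw.get("grid") or {})
        _check_keys(grid_raw, {"segments"}, "grid")
        if "segments" in grid_raw:
            grid = DoseGrid(segments=tuple(tuple(s) for s in grid_raw["segments"]))
        else:
            grid = default_dose_grid()

        return StudyConfig(
            population=population,
            pk=pk,
            schedules=tuple(raw.get("schedules", defaults["schedules"])),
            metrics=tuple(raw.get("metrics", defaults["metrics"])),
            baselines=tuple(raw.get("baselines", defaults["baselines"])),
            q48h_criterion=raw.get("q48h_criterion", defaults["q48h_criterion"]),
            mwf_criterion=raw.get("mwf_criterion", defaults["mwf_criterion"]),
            grid=grid,
            master_seed=raw.get("master_seed", defaults["master_seed"]),
            out_dir=raw.get("out_dir", defaults["out_dir"]),
            log_level=raw.get("log_level", defaults["log_level"]),
        )
    except ConfigError:
        raise
    except (TypeError, ValueError) as exc:
        raise ConfigError(str(exc)) from exc


def load_config(path) -> StudyConfig:
    """Load a YAML study configuration; missing keys fall back to defaults.

    An empty file yields the full default configuration.
    """
    text = Path(path).read_text()
    raw = yaml.safe_load(text)
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise ConfigError("configuration file must contain a YAML mapping")
    return _from_dict(raw)


def save_config(config: StudyConfig, path) -> None:
    """Write a configuration to YAML; round-trips through :func:`load_config`."""
    Path(path).write_text(yaml.safe_dump(_to_dict(config), sort_keys=True))


def config_hash(config: StudyConfig) -> str:
    """SHA-256 of the canonical JSON form (stable across sessions)."""
    canon = json.dumps(_to_dict(config), sort_keys=True, separators=(",", ":"))
    return hashlib.sha256(canon.encode()).hexdigest()
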