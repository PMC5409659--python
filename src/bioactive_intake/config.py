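"""YAML run configuration: file locations, filter rules, engine settings."""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .composition import FilterRules
from .engine import EngineConfig
from .stats import STATISTICS


@dataclass
class AssessmentConfig:
    """Everything one assessment run needs; paths resolved against the config file."""

    composition: Path
    survey: Path
    mapping: Path
    recipes: Path | None = None
    dataset: str = "STUDY"
    delimiter: str = ","
    decimal: str = "."
    survey_n_days: int | None = None
    filters: FilterRules = field(default_factory=FilterRules)
    engine: EngineConfig = field(default_factory=EngineConfig)


def load_config(path, **overrides) -> AssessmentConfig:
    """Read a key–value YAML config; keyword overrides win (CLI flags)."""
    path = Path(path)
    raw = yaml.safe_load(path.read_text()) or {}
    base = path.parent

    def resolve(key):
        value = raw.get(key)
        return (base / value) if value else None

    for p, key in ((resolve("composition"), "composition"), (resolve("survey"), "survey"),
                   (resolve("mapping"), "mapping")):
        if p is None:
            raise ValueError(f"config {path} must name a {key!r} file")

    filt = raw.get("filters", {})
    rules = FilterRules(
        exclude_parts=frozenset(filt.get("exclude_parts", ["peel"])),
        exclude_dry_weight=bool(filt.get("exclude_dry_weight", True)),
        processing_match=filt.get("processing_match", "any"),
    )
    eng = raw.get("engine", {})
    engine = EngineConfig(
        seed=eng.get("seed", 0),
        n_iterations=int(eng.get("iterations", 1)),
        bootstrap_reps=int(eng.get("bootstrap_reps", 1000)),
        statistics=tuple(eng.get("statistics", STATISTICS)),
        population=eng.get("population", "total"),
        draw_mode=eng.get("draw_mode", "event"),
    )
    cfg = AssessmentConfig(
        composition=resolve("composition"),
        survey=resolve("survey"),
        mapping=resolve("mapping"),
        recipes=resolve("recipes"),
        dataset=str(raw.get("dataset", "STUDY")),
        delimiter=str(raw.get("delimiter", ",")),
        decimal=str(raw.get("decimal", ".")),
        survey_n_days=raw.get("survey_n_days"),
        filters=rules,
        engine=engine,
    )
    for key, value in overrides.items():
        if value is None:
            continue
        if hasattr(cfg.engine, key):
            setattr(cfg.engine, key, value)
        elif hasattr(cfg, key):
            setattr(cfg, key, value)
        else:
            raise TypeError(f"unknown config override {key!r}")
    return cfg


@dataclass
class ScenarioFileSpec:
    """Parsed scenario definition: one compound, dose grid × probability grid."""

    compound: str
    doses_mg: tuple[float, ...]
    probabilities: tuple[float, ...] = (1.0,)
    events_per_day: int = 1
    target_group: str = "supplement_consumers"
    adoption_mode: str = "subject"


def load_scenario(path) -> ScenarioFileSpec | None:
    """Read a scenario YAML; returns None for an empty file (baseline only)."""
    raw = yaml.safe_load(Path(path).read_text())
    if not raw:
        return None
    return ScenarioFileSpec(
        compound=str(raw["compound"]),
        doses_mg=tuple(float(d) for d in raw["doses_mg"]),
        probabilities=tuple(float(p) for p in raw.get("probabilities", [1.0])),
        events_per_day=int(raw.get("events_per_day", 1)),
        target_group=str(raw.get("target_group", "supplement_consumers")),
        adoption_mode=str(raw.get("adoption_mode", "subject")),
    )
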