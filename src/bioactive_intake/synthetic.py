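"""Synthetic study generator with analytic ground truth.

Emulates the structure of a national food-consumption survey linked to a
composition database: a multi-day food diary (4 days by default, as in adult
diary surveys), survey weights, a supplement-consumer subpopulation, and a
multi-record concentration table per (plant, compound) pair including planted
peel-only and dry-weight rows for the refinement filters to remove.

Amounts and concentrations default to lognormal models — right-skewed and
positive, the usual shape of dietary data — parameterised by their *mean* on
the natural scale, so the analytic ground truth is immediate:

    E[intake mg/day] = E[amount g/day] × E[concentration mg/kg] / 1000

with E[amount g/day] = daily consumption probability × mean portion (plus
recipe-weighted dish contributions).  Every generated table carries this
ground truth alongside, so estimator output can be checked against closed
forms rather than against itself.  Consumption is independent across days
and foods; the generator does not emulate habit autocorrelation, day-of-week
effects, or correlated food choices.

The default conditions mirror a UK-adult-like diary: mean apple consumption
21 g/day (direct eating plus an apple-containing dish), chocolate 7.6 g/day,
orange juice 35 g/day; mean concentrations of 147 mg/kg epicatechin in
apple, 898 mg/kg in chocolate, and 640 mg/kg hesperidin in orange juice; and
a supplement-consumer fraction of 0.2586.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd

from .survey import SUPPLEMENT_GROUP


@dataclass(frozen=True)
class Quantity:
    """A positive random quantity: point mass, lognormal, or discrete list."""

    kind: str  # "point" | "lognormal" | "discrete"
    mean: float = 0.0
    sigma: float = 0.0  # log-scale sd for lognormal
    values: tuple[float, ...] = ()

    @classmethod
    def point(cls, value: float) -> "Quantity":
        return cls(kind="point", mean=float(value))

    @classmethod
    def lognormal(cls, mean: float, sigma: float) -> "Quantity":
        if mean <= 0 or sigma < 0 or not np.isfinite(mean) or not np.isfinite(sigma):
            raise ValueError("lognormal needs finite mean > 0 and sigma >= 0")
        return cls(kind="lognormal", mean=float(mean), sigma=float(sigma))

    @classmethod
    def discrete(cls, values) -> "Quantity":
        values = tuple(float(v) for v in values)
        if not values:
            raise ValueError("discrete quantity needs at least one value")
        return cls(kind="discrete", mean=float(np.mean(values)), values=values)

    @property
    def expectation(self) -> float:
        return self.mean

    def sample(self, rng: np.random.Generator, size: int) -> np.ndarray:
        if self.kind == "point":
            return np.full(size, self.mean)
        if self.kind == "lognormal":
            mu = np.log(self.mean) - self.sigma**2 / 2  # E = mean by construction
            return rng.lognormal(mu, self.sigma, size)
        if self.kind == "discrete":
            return np.asarray(self.values)[rng.integers(0, len(self.values), size)]
        raise ValueError(f"unknown quantity kind {self.kind!r}")


@dataclass(frozen=True)
class FoodSpec:
    """Per-food daily consumption model: Bernoulli day, then a portion draw."""

    food_code: str
    plant: str
    daily_probability: float
    amount_g: Quantity
    food_group: str = "Plant foods"

    def __post_init__(self) -> None:
        if not 0 <= self.daily_probability <= 1:
            raise ValueError("daily_probability must be in [0, 1]")

    @property
    def expected_g_day(self) -> float:
        return self.daily_probability * self.amount_g.expectation


@dataclass(frozen=True)
class DishSpec(FoodSpec):
    """A composite dish; ``components`` are (plant, weight fraction) pairs."""

    components: tuple[tuple[str, float], ...] = ()

    def __post_init__(self) -> None:
        super().__post_init__()
        if sum(f for _, f in self.components) > 1 + 1e-9:
            raise ValueError("dish component fractions must sum to <= 1")


@dataclass(frozen=True)
class ConcentrationSpec:
    """Concentration model for one (plant, compound) pair, plus planted rows."""

    plant: str
    compound: str
    level_mg_kg: Quantity
    compound_class: str = ""
    n_records: int = 20
    n_peel: int = 0
    n_dry: int = 0

    @property
    def expectation(self) -> float:
        return self.level_mg_kg.expectation


def _default_foods() -> tuple[FoodSpec, ...]:
    return (
        FoodSpec("F-APPLE", "Apple", 0.20, Quantity.lognormal(90.0, 0.5), "Fruit"),
        FoodSpec("F-CHOC", "Chocolate", 0.19, Quantity.lognormal(40.0, 0.6), "Confectionery"),
        FoodSpec("F-OJ", "Orange juice", 0.25, Quantity.lognormal(140.0, 0.4), "Beverages"),
        DishSpec(
            "D-APPLEPIE", "Apple pie", 0.10, Quantity.lognormal(120.0, 0.4), "Dishes",
            components=(("Apple", 0.25),),
        ),
    )


def _default_concentrations() -> tuple[ConcentrationSpec, ...]:
    return (
        ConcentrationSpec("Apple", "Epicatechin", Quantity.lognormal(147.0, 0.4), "Flavanols"),
        ConcentrationSpec("Chocolate", "Epicatechin", Quantity.lognormal(898.0, 0.4), "Flavanols"),
        ConcentrationSpec("Orange juice", "Hesperidin", Quantity.lognormal(640.0, 0.4), "Flavanones"),
    )


@dataclass(frozen=True)
class GeneratorSpec:
    """Full study definition; ``seed`` fixes every random draw."""

    n_subjects: int = 1000
    n_days: int = 4
    weight_scheme: str = "uniform"  # or "lognormal" (mean 1)
    foods: tuple[FoodSpec, ...] = field(default_factory=_default_foods)
    concentrations: tuple[ConcentrationSpec, ...] = field(
        default_factory=_default_concentrations
    )
    supplement_fraction: float = 0.2586
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 1 or self.n_days < 1:
            raise ValueError("n_subjects and n_days must be >= 1")
        if not 0 <= self.supplement_fraction <= 1:
            raise ValueError("supplement_fraction must be in [0, 1]")
        if self.weight_scheme not in ("uniform", "lognormal"):
            raise ValueError("weight_scheme must be 'uniform' or 'lognormal'")

    # -- mapping / recipe tables the readers consume -----------------------
    def mapping(self) -> dict[str, str]:
        return {
            f.food_code: f.plant for f in self.foods if not isinstance(f, DishSpec)
        }

    def recipes(self) -> pd.DataFrame:
        rows = [
            (d.food_code, plant, fraction)
            for d in self.foods
            if isinstance(d, DishSpec)
            for plant, fraction in d.components
        ]
        return pd.DataFrame(rows, columns=["dish_food_code", "plant_name", "fraction"])

    def expected_g_day(self) -> dict[str, float]:
        """Analytic mean daily consumption per plant, dishes disaggregated."""
        out: dict[str, float] = {}
        for f in self.foods:
            if isinstance(f, DishSpec):
                for plant, fraction in f.components:
                    out[plant] = out.get(plant, 0.0) + f.expected_g_day * fraction
            else:
                out[f.plant] = out.get(f.plant, 0.0) + f.expected_g_day
        return out


def generate_survey(spec: GeneratorSpec) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Simulate the diary: (subjects, events, ground_truth).

    ground_truth holds the analytic expected consumption per plant, the
    realized supplement-consumer ids and fraction, and the per-subject
    weights actually drawn.
    """
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 101]))
    ids = np.array([f"S{i:05d}" for i in range(1, spec.n_subjects + 1)])
    if spec.weight_scheme == "uniform":
        weights = np.ones(spec.n_subjects)
    else:
        weights = rng.lognormal(-0.3**2 / 2, 0.3, spec.n_subjects)

    subjects = pd.DataFrame(
        {"subject_id": ids, "survey_weight": weights, "n_survey_days": spec.n_days}
    )

    frames: list[pd.DataFrame] = []
    for f in spec.foods:
        eaten = rng.random((spec.n_subjects, spec.n_days)) < f.daily_probability
        si, di = np.nonzero(eaten)
        amounts = f.amount_g.sample(rng, si.size)
        frames.append(
            pd.DataFrame(
                {
                    "subject_id": ids[si],
                    "day": di + 1,
                    "food_code": f.food_code,
                    "amount_g": amounts,
                    "food_group": f.food_group,
                }
            )
        )

    is_consumer = rng.random(spec.n_subjects) < spec.supplement_fraction
    consumer_ids = ids[is_consumer]
    if consumer_ids.size:
        frames.append(
            pd.DataFrame(
                {
                    "subject_id": consumer_ids,
                    "day": rng.integers(1, spec.n_days + 1, consumer_ids.size),
                    "food_code": "SUPP-MULTI",
                    "amount_g": 1.0,
                    "food_group": SUPPLEMENT_GROUP,
                }
            )
        )

    events = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame(
        columns=["subject_id", "day", "food_code", "amount_g", "food_group"]
    )
    events = events.sort_values(["subject_id", "day", "food_code"], kind="stable").reset_index(
        drop=True
    )
    ground_truth = {
        "expected_g_day": spec.expected_g_day(),
        "supplement_consumers": tuple(consumer_ids),
        "realized_supplement_fraction": float(is_consumer.mean()),
        "weights": dict(zip(ids, weights)),
    }
    return subjects, events, ground_truth


_EXPORT_COLUMNS = [
    "Plant name", "Scientific name", "Compound", "Compound class", "Level", "Unit",
    "Part", "Plant description", "Shape, state or form", "EuroFIR classification",
    "Heat treatment", "Cooking method", "Treatment applied", "Preservation method",
    "Quality code", "Reference",
]


def generate_concentrations(
    spec: GeneratorSpec, *, mixed_units: bool = False
) -> tuple[pd.DataFrame, dict]:
    """Simulate the composition export: (table, ground_truth).

    The table follows the delimited-export schema the reader consumes.  For
    each pair, ``n_records`` clean fresh-weight whole-food rows are drawn
    from the pair's level model; ``n_peel`` peel-only rows and ``n_dry``
    dry-weight rows are planted so refinement filters have something to
    remove.  With ``mixed_units`` every third clean row is expressed as
    mg/100 g to exercise unit harmonization.  ground_truth records each
    pair's model mean, the drawn clean levels, and the planted-row counts.
    """
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 202]))
    rows: list[dict] = []
    truth: dict[tuple[str, str], dict] = {}
    ref = 0

    def base_row(cs: ConcentrationSpec, level: float, unit: str, part: str) -> dict:
        nonlocal ref
        ref += 1
        return {
            "Plant name": cs.plant,
            "Scientific name": f"{cs.plant} (syn.)",
            "Compound": cs.compound,
            "Compound class": cs.compound_class,
            "Level": level,
            "Unit": unit,
            "Part": part,
            "Plant description": "cultivar mix",
            "Shape, state or form": "whole",
            "EuroFIR classification": "fruit/vegetable product",
            "Heat treatment": "none",
            "Cooking method": "none",
            "Treatment applied": "none",
            "Preservation method": "none",
            "Quality code": "A",
            "Reference": f"R{ref:04d}",
        }

    for cs in spec.concentrations:
        clean = cs.level_mg_kg.sample(rng, cs.n_records)
        for i, level in enumerate(clean):
            if mixed_units and i % 3 == 2:
                rows.append(base_row(cs, level / 10.0, "mg/100 g", "whole fruit"))
            else:
                rows.append(base_row(cs, level, "mg/kg", "whole fruit"))
        for level in cs.level_mg_kg.sample(rng, cs.n_peel) * 5.0:
            rows.append(base_row(cs, level, "mg/kg", "peel"))
        for level in cs.level_mg_kg.sample(rng, cs.n_dry) * 6.0:
            rows.append(base_row(cs, level, "mg/kg dry weight", "whole fruit"))
        truth[(cs.plant, cs.compound)] = {
            "true_mean_mg_kg": cs.expectation,
            "clean_levels_mg_kg": tuple(float(v) for v in clean),
            "n_clean": cs.n_records,
            "n_planted": cs.n_peel + cs.n_dry,
        }
    return pd.DataFrame(rows, columns=_EXPORT_COLUMNS), truth


def ground_truth_intake(spec: GeneratorSpec) -> dict[tuple[str, str], float]:
    """Closed-form expected mean intake (mg/day) per (plant, compound).

    Amount and concentration draws are independent, so the expectation
    factorizes: E[g/day] × E[mg/kg] / 1000.
    """
    g_day = spec.expected_g_day()
    return {
        (cs.plant, cs.compound): g_day.get(cs.plant, 0.0) * cs.expectation / 1000.0
        for cs in spec.concentrations
    }


def write_fixture_set(spec: GeneratorSpec, directory, *, mixed_units: bool = False) -> dict:
    """Write a complete toy study (survey, composition, mapping, recipes) as CSV.

    Returns the combined ground truth.  The files use exactly the dialects
    the package readers consume.
    """
    from pathlib import Path

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    subjects, events, survey_truth = generate_survey(spec)
    table, conc_truth = generate_concentrations(spec, mixed_units=mixed_units)

    # a diary lists only consumed foods, so a subject with an empty diary would
    # vanish from the file; anchor them with a zero-amount row to keep
    # total-population semantics (their zeros count toward the mean)
    missing = subjects.loc[
        ~subjects["subject_id"].isin(events["subject_id"]), "subject_id"
    ]
    if len(missing):
        anchors = pd.DataFrame(
            {
                "subject_id": missing,
                "day": 1,
                "food_code": "NO-CONSUMPTION",
                "amount_g": 0.0,
                "food_group": "",
            }
        )
        events = pd.concat([events, anchors], ignore_index=True)

    survey_out = events.merge(
        subjects.rename(columns={"survey_weight": "weight"})[
            ["subject_id", "weight", "n_survey_days"]
        ],
        on="subject_id",
    ).rename(columns={"n_survey_days": "n_days"})
    survey_out.to_csv(directory / "survey.csv", index=False)
    table.to_csv(directory / "composition.csv", index=False)
    pd.DataFrame(
        sorted(spec.mapping().items()), columns=["food_code", "plant_name"]
    ).to_csv(directory / "mapping.csv", index=False)
    spec.recipes().to_csv(directory / "recipes.csv", index=False)
    return {
        "survey": survey_truth,
        "concentrations": {f"{p}|{c}": v for (p, c), v in conc_truth.items()},
        "expected_intake_mg_day": {
            f"{p}|{c}": v for (p, c), v in ground_truth_intake(spec).items()
        },
    }
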