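"""Consumption surveys: reading diaries, food→plant mapping, recipe disaggregation.

A consumption survey is a multi-day food diary: each subject reports, per
diary day, the foods eaten and the amount in grams.  Subjects may carry
sampling weights (1.0 when the survey is unweighted).  Before intakes can be
simulated, consumed food codes must be resolved to the plant names that the
composition data is keyed by — either directly (a raw apple is "apple") or
through a recipe that breaks a composite dish into ingredient plants, each a
fixed weight fraction of the dish.  Subjects who logged at least one eating
occasion from the "Dietary Supplements" food group are flagged as supplement
consumers; scenario modelling targets that subpopulation.

Tabular data is held in pandas DataFrames; the dataclasses below document the
row schemas and give a typed surface for single-row construction in tests.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

SUPPLEMENT_GROUP = "Dietary Supplements"

SUBJECT_COLUMNS = ["subject_id", "survey_weight", "n_survey_days"]
EVENT_COLUMNS = ["subject_id", "day", "food_code", "amount_g", "food_group"]
MAPPED_COLUMNS = ["subject_id", "day", "plant", "amount_g", "provenance"]


@dataclass(frozen=True)
class Subject:
    subject_id: str
    survey_weight: float = 1.0
    n_survey_days: int = 4
    supplement_consumer: bool = False

    def __post_init__(self) -> None:
        if self.survey_weight <= 0:
            raise ValueError("survey_weight must be > 0")
        if self.n_survey_days < 1:
            raise ValueError("n_survey_days must be >= 1")


@dataclass(frozen=True)
class ConsumptionEvent:
    subject_id: str
    day: int
    food_code: str
    amount_g: float
    food_group: str = ""

    def __post_init__(self) -> None:
        if self.amount_g < 0:
            raise ValueError("amount_g must be >= 0")
        if self.day < 1:
            raise ValueError("day indices are 1-based")


@dataclass(frozen=True)
class RecipeComponent:
    """One ingredient plant of a composite dish, as a weight fraction."""

    dish_food_code: str
    plant_name: str
    fraction: float

    def __post_init__(self) -> None:
        if not 0 < self.fraction <= 1:
            raise ValueError("fraction must be in (0, 1]")


class SurveyValidationError(ValueError):
    """Survey rows violate the diary schema (negative amounts, day out of span)."""


class RecipeError(ValueError):
    """A dish's component fractions sum to more than 1."""


def read_survey(
    path,
    *,
    delimiter: str = ",",
    n_days: int | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Read a diary file into (subjects, events) frames.

    Expected columns: subject_id, weight, day, food_code, amount_g,
    food_group.  A missing weight column defaults every weight to 1.0 with a
    warning.  ``n_days`` (or an ``n_days`` column) fixes the diary span; when
    absent, each subject's span is inferred as their maximum reported day.
    Duplicate (subject, day, food) rows are kept — a food may recur within a
    day.  Negative amounts and days outside the span raise
    :class:`SurveyValidationError` naming the offending rows.
    """
    frame = pd.read_csv(path, sep=delimiter)
    required = ["subject_id", "day", "food_code", "amount_g"]
    missing = [c for c in required if c not in frame.columns]
    if missing:
        raise SurveyValidationError(f"survey {path} is missing columns: {', '.join(missing)}")
    if "weight" not in frame.columns:
        logger.warning("survey %s has no weight column; defaulting all weights to 1.0", path)
        frame["weight"] = 1.0
    if "food_group" not in frame.columns:
        frame["food_group"] = ""

    bad_amount = frame.index[frame["amount_g"] < 0]
    if len(bad_amount):
        raise SurveyValidationError(
            f"negative amount_g on rows {list(bad_amount[:10])} of {path}"
        )

    frame["subject_id"] = frame["subject_id"].astype(str)
    subjects = (
        frame.groupby("subject_id", sort=True)
        .agg(survey_weight=("weight", "first"), max_day=("day", "max"))
        .reset_index()
    )
    if n_days is not None:
        subjects["n_survey_days"] = int(n_days)
    elif "n_days" in frame.columns:
        per_subject = frame.groupby("subject_id", sort=True)["n_days"].first()
        subjects["n_survey_days"] = per_subject.to_numpy(dtype=int)
    else:
        subjects["n_survey_days"] = subjects["max_day"].astype(int)

    over = subjects[subjects["max_day"] > subjects["n_survey_days"]]
    if len(over):
        raise SurveyValidationError(
            "day index exceeds the diary span for subjects: "
            + ", ".join(over["subject_id"].head(10))
        )
    if (subjects["survey_weight"] <= 0).any():
        raise SurveyValidationError("survey weights must be strictly positive")

    events = frame[EVENT_COLUMNS].copy()
    return subjects[SUBJECT_COLUMNS], events


@dataclass
class MappingResult:
    """Mapped events plus a coverage report (fraction of grams mapped)."""

    events: pd.DataFrame  # MAPPED_COLUMNS schema
    gram_coverage: float
    unmapped_codes: tuple[str, ...]

    def __iter__(self):
        return iter((self.events, self.gram_coverage, self.unmapped_codes))


def _recipe_frame(recipes) -> pd.DataFrame:
    if isinstance(recipes, pd.DataFrame):
        frame = recipes.rename(columns={"plant": "plant_name"}).copy()
    else:
        frame = pd.DataFrame(
            [(r.dish_food_code, r.plant_name, r.fraction) for r in recipes],
            columns=["dish_food_code", "plant_name", "fraction"],
        )
    if len(frame):
        sums = frame.groupby("dish_food_code")["fraction"].sum()
        bad = sums[sums > 1 + 1e-9]
        if len(bad):
            raise RecipeError(
                "component fractions exceed 1 for dishes: " + ", ".join(bad.index.astype(str))
            )
    return frame


def map_events(
    events: pd.DataFrame,
    mapping: Mapping[str, str],
    recipes=(),
) -> MappingResult:
    """Resolve consumed food codes to plant amounts.

    Directly mapped codes yield one mapped event with the full amount; a dish
    with k recipe components yields k events with ``amount × fraction`` each.
    Codes that are neither mapped nor in a recipe are dropped (surveys contain
    many foods outside the composition food list); the result's
    ``gram_coverage`` reports the fraction of consumed grams that survived.
    Mapping is deterministic: input order, then recipe component order.
    """
    recipe_frame = _recipe_frame(recipes)
    recipe_codes = set(recipe_frame["dish_food_code"]) if len(recipe_frame) else set()

    direct = events[events["food_code"].isin(mapping.keys())].copy()
    direct["plant"] = direct["food_code"].map(mapping)
    direct["provenance"] = "direct"
    direct = direct[["subject_id", "day", "plant", "amount_g", "provenance"]]

    dish = events[events["food_code"].isin(recipe_codes)]
    if len(dish):
        expanded = dish.merge(
            recipe_frame, left_on="food_code", right_on="dish_food_code", how="inner"
        )
        expanded["amount_g"] = expanded["amount_g"] * expanded["fraction"]
        expanded["plant"] = expanded["plant_name"]
        expanded["provenance"] = "recipe:" + expanded["dish_food_code"].astype(str)
        expanded = expanded[["subject_id", "day", "plant", "amount_g", "provenance"]]
        expanded.columns = MAPPED_COLUMNS
    else:
        expanded = None

    direct.columns = MAPPED_COLUMNS
    mapped = (
        pd.concat([direct, expanded], ignore_index=True) if expanded is not None else direct
    )

    covered = events["food_code"].isin(mapping.keys() | recipe_codes)
    total_g = float(events["amount_g"].sum())
    coverage = float(events.loc[covered, "amount_g"].sum()) / total_g if total_g > 0 else 1.0
    unmapped = tuple(sorted(events.loc[~covered, "food_code"].astype(str).unique()))
    if unmapped:
        logger.info(
            "dropped %d unmapped food codes (%.1f%% of grams mapped)",
            len(unmapped), 100 * coverage,
        )
    return MappingResult(events=mapped, gram_coverage=coverage, unmapped_codes=unmapped)


def flag_supplement_consumers(subjects: pd.DataFrame, events: pd.DataFrame) -> pd.DataFrame:
    """Mark subjects with >= 1 eating occasion from the Dietary Supplements group."""
    groups = events["food_group"].astype(str).str.strip().str.lower()
    consumers = set(events.loc[groups == SUPPLEMENT_GROUP.lower(), "subject_id"])
    out = subjects.copy()
    out["supplement_consumer"] = out["subject_id"].isin(consumers)
    return out
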