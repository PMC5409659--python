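"""What-if supplementation scenarios.

A scenario inserts a hypothetical product — e.g. a polyphenol-extract capsule
with a declared compound dose — into a survey population's diet and asks how
the population intake distribution shifts.  Eligible subjects (by default the
supplement consumers, who are assumed readiest to adopt such a product) each
adopt the product with a consumption probability p; an adopter takes
``events_per_day`` units on every diary day, each contributing the declared
``dose_mg`` directly, with no concentration sampling.

The mean-shift identity makes the expected effect transparent:

    E[scenario mean] − baseline mean = dose × events/day × eligible weighted fraction × p

exact when p = 1 and within binomial Monte Carlo error otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .engine import EngineConfig, IntakeResult
from .stats import bootstrap_summary, weighted_mean, weighted_summary
from .survey import SUPPLEMENT_GROUP


@dataclass(frozen=True)
class ScenarioSpec:
    """A product-insertion rule: what is added, to whom, how often."""

    compound: str
    dose_mg: float
    events_per_day: int = 1
    target_group: str = "supplement_consumers"  # or "all"
    consumption_probability: float = 1.0
    adoption_mode: str = "subject"  # one Bernoulli per subject; or "day", one per diary day

    def __post_init__(self) -> None:
        if self.dose_mg <= 0:
            raise ValueError("dose_mg must be > 0")
        if self.events_per_day < 1:
            raise ValueError("events_per_day must be >= 1")
        if not 0 <= self.consumption_probability <= 1:
            raise ValueError("consumption_probability must be in [0, 1]")
        if self.target_group not in ("supplement_consumers", "all"):
            raise ValueError("target_group must be 'supplement_consumers' or 'all'")
        if self.adoption_mode not in ("subject", "day"):
            raise ValueError("adoption_mode must be 'subject' or 'day'")

    @property
    def food_code(self) -> str:
        return f"capsule:{self.compound}:{self.dose_mg:g}mg"


@dataclass
class ScenarioApplication:
    """Augmented survey after inserting the product."""

    events: pd.DataFrame  # original events + capsule eating events
    direct_doses: pd.DataFrame  # subject_id, day, compound, dose_mg
    selected_subjects: tuple[str, ...]


def eligible_subjects(subjects: pd.DataFrame, spec: ScenarioSpec) -> pd.Series:
    """Boolean eligibility mask over the subject frame."""
    if spec.target_group == "all":
        return pd.Series(True, index=subjects.index)
    if "supplement_consumer" not in subjects.columns:
        raise ValueError(
            "supplement_consumer flags missing; run flag_supplement_consumers first"
        )
    return subjects["supplement_consumer"].astype(bool)


def apply_scenario(
    subjects: pd.DataFrame,
    events: pd.DataFrame,
    spec: ScenarioSpec,
    rng: np.random.Generator,
) -> ScenarioApplication:
    """Insert capsule eating events for the subjects who adopt the product.

    One Bernoulli(p) draw per eligible subject decides adoption (an adopter
    takes the product on every diary day); ``adoption_mode="day"`` instead
    draws per subject-day.  The returned event rows carry the
    Dietary Supplements food group; the parallel ``direct_doses`` frame feeds
    :func:`bioactive_intake.engine.subject_daily_intakes` fixed-dose intakes.
    """
    mask = eligible_subjects(subjects, spec)
    eligible = subjects.loc[mask, ["subject_id", "n_survey_days"]]

    rows: list[tuple[str, int]] = []  # (subject_id, day) of each capsule event-day
    p = spec.consumption_probability
    if spec.adoption_mode == "subject":
        adopt = rng.random(len(eligible)) < p
        for (sid, ndays) in eligible.to_numpy()[adopt]:
            rows.extend((str(sid), day) for day in range(1, int(ndays) + 1))
    else:
        for sid, ndays in eligible.to_numpy():
            for day in range(1, int(ndays) + 1):
                if rng.random() < p:
                    rows.append((str(sid), day))

    per_event = [
        (sid, day) for sid, day in rows for _ in range(spec.events_per_day)
    ]
    capsules = pd.DataFrame(per_event, columns=["subject_id", "day"])
    capsules["food_code"] = spec.food_code
    capsules["amount_g"] = 0.0  # capsule mass is not food mass; dose is direct
    capsules["food_group"] = SUPPLEMENT_GROUP

    direct = capsules[["subject_id", "day"]].copy()
    direct["compound"] = spec.compound
    direct["dose_mg"] = spec.dose_mg

    augmented = pd.concat(
        [events, capsules[list(events.columns)]], ignore_index=True
    ) if len(capsules) else events.copy()
    selected = tuple(dict.fromkeys(sid for sid, _ in rows))
    return ScenarioApplication(events=augmented, direct_doses=direct, selected_subjects=selected)


def expected_scenario_mean(
    baseline_mean_mg_day: float,
    eligible_weighted_fraction: float,
    spec: ScenarioSpec,
) -> float:
    """Closed-form scenario population mean from the mean-shift identity."""
    if not 0 <= eligible_weighted_fraction <= 1:
        raise ValueError("eligible_weighted_fraction must be in [0, 1]")
    shift = (
        spec.dose_mg
        * spec.events_per_day
        * eligible_weighted_fraction
        * spec.consumption_probability
    )
    return baseline_mean_mg_day + shift


@dataclass
class ScenarioComparison:
    """Side-by-side baseline vs scenario summary plus the mean shift."""

    table: pd.DataFrame  # rows baseline/scenario; statistic + SE columns
    mean_shift: float


def compare_scenarios(
    baseline: IntakeResult,
    scenario: IntakeResult,
    subjects: pd.DataFrame,
    compound: str,
    config: EngineConfig | None = None,
) -> ScenarioComparison:
    """Summarize one compound's intake under baseline and scenario.

    Both results must cover the same subjects.  Statistics are weighted over
    the total population with bootstrap SEs; identical bootstrap resamples
    are used for both rows, so the SE of the shift is not inflated by
    resampling noise.
    """
    if baseline.subject_order != scenario.subject_order:
        raise ValueError("baseline and scenario cover different subjects")
    config = config or EngineConfig()
    order = pd.Index(baseline.subject_order)
    weights = (
        subjects.set_index(subjects["subject_id"].astype(str))["survey_weight"]
        .reindex(order)
        .to_numpy(dtype=float)
    )
    stats = tuple(s for s in config.statistics if s in ("mean", "P25", "median", "P95"))
    rows = {}
    for label, result in (("baseline", baseline), ("scenario", scenario)):
        values = result.compound_intakes(compound).reindex(order).fillna(0.0).to_numpy()
        summary = bootstrap_summary(
            values, weights, stats, B=config.bootstrap_reps, seed=config.seed
        )
        row: dict[str, float] = {}
        for s in stats:
            row[s] = summary[s]
            row[f"{s}_se"] = summary.standard_errors[s]
        rows[label] = row
    table = pd.DataFrame.from_dict(rows, orient="index")
    return ScenarioComparison(
        table=table, mean_shift=float(rows["scenario"]["mean"] - rows["baseline"]["mean"])
    )
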