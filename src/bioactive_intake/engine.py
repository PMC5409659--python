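"""Probabilistic intake computation.

For every mapped eating event the engine draws one concentration from the
discrete distribution of the event's (plant, compound) pair — every
analytical record is equally likely — and converts grams consumed into a
compound intake in mg (``g × mg/kg / 1000``).  A subject's mean daily intake
divides the total over the diary by *all* diary days, so days without
consumption pull the mean down: that is the total-population convention used
for survey intake tables.  Population summaries (weighted mean, percentiles,
bootstrap SEs) are layered on top via :mod:`bioactive_intake.stats`.

Two sampling granularities are supported: a fresh draw per eating event
(default — maximal variability propagation) or one draw per subject-day
shared by all same-plant events of that day.  The expectation is identical
either way; only higher moments differ.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .composition import ConcentrationDistribution
from .stats import STATISTICS, SummaryStatistics, bootstrap_summary, weighted_summary

logger = logging.getLogger(__name__)

#: Label used in per-food breakdowns for fixed-dose (capsule) contributions.
DIRECT_SOURCE = "(supplement)"


@dataclass
class EngineConfig:
    """Monte Carlo controls. Same seed → identical output, bit for bit."""

    seed: int | None = 0
    n_iterations: int = 1
    bootstrap_reps: int = 1000
    statistics: tuple[str, ...] = STATISTICS
    population: str = "total"  # or "consumers"
    draw_mode: str = "event"  # or "day"
    keep_iteration_draws: bool = False

    def __post_init__(self) -> None:
        if self.n_iterations < 1:
            raise ValueError("n_iterations must be >= 1")
        if self.bootstrap_reps < 2:
            raise ValueError("bootstrap_reps must be >= 2")
        if self.population not in ("total", "consumers"):
            raise ValueError("population must be 'total' or 'consumers'")
        if self.draw_mode not in ("event", "day"):
            raise ValueError("draw_mode must be 'event' or 'day'")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


@dataclass
class IntakeResult:
    """Per-subject mean daily intakes (mg/day) and food consumption (g/day).

    ``per_subject`` is zero-filled: every subject appears for every compound,
    so total-population and consumers-only summaries can both be derived.
    ``draws`` (optional) holds the per-iteration population matrices, one
    ``(n_iterations, n_subjects)`` array per compound, aligned with
    ``subject_order``.
    """

    per_subject: pd.DataFrame  # subject_id, compound, intake_mg_day
    per_subject_food: pd.DataFrame  # subject_id, plant, compound, intake_mg_day
    food_consumption: pd.DataFrame  # subject_id, plant, g_day
    scope: str = "total"
    n_iterations: int = 1
    subject_order: tuple[str, ...] = ()
    draws: dict[str, np.ndarray] = field(default_factory=dict)

    def compound_intakes(self, compound: str) -> pd.Series:
        """Per-subject mg/day for one compound, indexed by subject_id."""
        sub = self.per_subject[self.per_subject["compound"] == compound]
        return sub.set_index("subject_id")["intake_mg_day"]

    @property
    def compounds(self) -> tuple[str, ...]:
        return tuple(self.per_subject["compound"].unique())


def sample_concentration(dist: ConcentrationDistribution, rng: np.random.Generator) -> float:
    """Draw one concentration (mg/kg), uniform over the distribution's records."""
    if len(dist) == 0:  # defensive; the type forbids it
        raise ValueError("cannot sample from an empty concentration distribution")
    return float(dist.values[rng.integers(0, len(dist))])


def event_intake(plant_amount_g: float, concentration_mg_kg: float) -> float:
    """Intake in mg from one eating event: grams × (mg/kg) / 1000."""
    if plant_amount_g < 0 or concentration_mg_kg < 0:
        raise ValueError("amount and concentration must be >= 0")
    return plant_amount_g * concentration_mg_kg / 1000.0


def implied_consumption(mean_intake_mg_day: float, mean_concentration_mg_kg: float) -> float:
    """Food consumption (g/day) implied by an intake and a mean concentration."""
    if mean_concentration_mg_kg <= 0:
        raise ValueError("mean concentration must be > 0")
    if mean_intake_mg_day < 0:
        raise ValueError("intake must be >= 0")
    return 1000.0 * mean_intake_mg_day / mean_concentration_mg_kg


def _per_iteration_totals(
    grams: np.ndarray,
    subj_idx: np.ndarray,
    day: np.ndarray,
    dist: ConcentrationDistribution,
    rng: np.random.Generator,
    n_subjects: int,
    n_iterations: int,
    draw_mode: str,
) -> np.ndarray:
    """Total mg per subject per iteration for one (plant, compound) pair."""
    m = grams.size
    if draw_mode == "day":
        # one draw per (subject, day), shared across that day's same-plant events
        keys = subj_idx.astype(np.int64) * (int(day.max()) + 1) + day
        uniq, inverse = np.unique(keys, return_inverse=True)
        idx = rng.integers(0, len(dist), size=(n_iterations, uniq.size))
        conc = dist.values[idx][:, inverse]
    else:
        idx = rng.integers(0, len(dist), size=(n_iterations, m))
        conc = dist.values[idx]
    contrib = conc * (grams / 1000.0)
    totals = np.empty((n_iterations, n_subjects))
    for it in range(n_iterations):
        totals[it] = np.bincount(subj_idx, weights=contrib[it], minlength=n_subjects)
    return totals


def subject_daily_intakes(
    subjects: pd.DataFrame,
    mapped_events: pd.DataFrame,
    distributions: Mapping[tuple[str, str], ConcentrationDistribution],
    config: EngineConfig | None = None,
    *,
    rng: np.random.Generator | None = None,
    direct_doses: pd.DataFrame | None = None,
) -> IntakeResult:
    """Simulate mean daily intakes for every subject and compound.

    Parameters
    ----------
    subjects
        Frame with subject_id, survey_weight, n_survey_days.
    mapped_events
        Frame with subject_id, day, plant, amount_g (see
        :func:`bioactive_intake.survey.map_events`).
    distributions
        Discrete concentration distributions keyed by (plant, compound).
    direct_doses
        Optional fixed-dose events (subject_id, day, compound, dose_mg) that
        bypass concentration sampling — supplement capsules with a declared
        compound content per unit.

    With ``config.n_iterations > 1`` the per-subject value is the mean across
    iterations of the per-iteration mean daily intake.
    """
    config = config or EngineConfig()
    rng = rng if rng is not None else config.rng()

    subject_ids = subjects["subject_id"].astype(str).to_numpy()
    n_subjects = subject_ids.size
    n_days = subjects["n_survey_days"].to_numpy(dtype=float)
    pos = {s: i for i, s in enumerate(subject_ids)}

    events = mapped_events.copy()
    unknown = set(events["subject_id"].astype(str)) - set(subject_ids)
    if unknown:
        raise ValueError(f"events reference unknown subjects: {sorted(unknown)[:5]}")
    events["_si"] = events["subject_id"].astype(str).map(pos)

    per_subject_food_rows: list[pd.DataFrame] = []
    totals_by_compound: dict[str, np.ndarray] = {}

    for (plant, compound), dist in distributions.items():
        ev = events[events["plant"] == plant]
        if not len(ev):
            continue
        totals = _per_iteration_totals(
            ev["amount_g"].to_numpy(dtype=float),
            ev["_si"].to_numpy(dtype=np.int64),
            ev["day"].to_numpy(dtype=np.int64),
            dist,
            rng,
            n_subjects,
            config.n_iterations,
            config.draw_mode,
        )
        daily = totals / n_days  # (n_iter, n_subjects) mg/day
        acc = totals_by_compound.setdefault(compound, np.zeros_like(daily))
        acc += daily
        mean_daily = daily.mean(axis=0)
        nz = mean_daily > 0
        per_subject_food_rows.append(
            pd.DataFrame(
                {
                    "subject_id": subject_ids[nz],
                    "plant": plant,
                    "compound": compound,
                    "intake_mg_day": mean_daily[nz],
                }
            )
        )

    if direct_doses is not None and len(direct_doses):
        dd = direct_doses.copy()
        dd["_si"] = dd["subject_id"].astype(str).map(pos)
        if dd["_si"].isna().any():
            raise ValueError("direct doses reference unknown subjects")
        for compound, grp in dd.groupby("compound", sort=True):
            totals = np.bincount(
                grp["_si"].to_numpy(dtype=np.int64),
                weights=grp["dose_mg"].to_numpy(dtype=float),
                minlength=n_subjects,
            )
            daily = np.broadcast_to(totals / n_days, (config.n_iterations, n_subjects)).copy()
            acc = totals_by_compound.setdefault(str(compound), np.zeros_like(daily))
            acc += daily
            nz = daily[0] > 0
            per_subject_food_rows.append(
                pd.DataFrame(
                    {
                        "subject_id": subject_ids[nz],
                        "plant": DIRECT_SOURCE,
                        "compound": str(compound),
                        "intake_mg_day": daily[0][nz],
                    }
                )
            )

    compounds = sorted(totals_by_compound)
    per_subject = pd.DataFrame(
        {
            "subject_id": np.tile(subject_ids, len(compounds)) if compounds else [],
            "compound": np.repeat(compounds, n_subjects) if compounds else [],
            "intake_mg_day": (
                np.concatenate([totals_by_compound[c].mean(axis=0) for c in compounds])
                if compounds
                else []
            ),
        }
    )
    per_subject_food = (
        pd.concat(per_subject_food_rows, ignore_index=True)
        if per_subject_food_rows
        else pd.DataFrame(columns=["subject_id", "plant", "compound", "intake_mg_day"])
    )

    cons = events.groupby(["subject_id", "plant"], sort=True)["amount_g"].sum().reset_index()
    cons["_si"] = cons["subject_id"].astype(str).map(pos)
    cons["g_day"] = cons["amount_g"] / n_days[cons["_si"].to_numpy(dtype=np.int64)]
    food_consumption = cons[["subject_id", "plant", "g_day"]]

    draws = (
        {c: totals_by_compound[c] for c in compounds} if config.keep_iteration_draws else {}
    )
    return IntakeResult(
        per_subject=per_subject,
        per_subject_food=per_subject_food,
        food_consumption=food_consumption,
        scope="total",
        n_iterations=config.n_iterations,
        subject_order=tuple(subject_ids),
        draws=draws,
    )


def _aligned(
    series: pd.Series, subjects: pd.DataFrame
) -> tuple[np.ndarray, np.ndarray]:
    """Zero-fill a per-subject series over the full subject frame; return (values, weights)."""
    idx = subjects["subject_id"].astype(str)
    values = series.reindex(idx).fillna(0.0).to_numpy(dtype=float)
    weights = subjects["survey_weight"].to_numpy(dtype=float)
    return values, weights


def summarize_intakes(
    result: IntakeResult,
    subjects: pd.DataFrame,
    config: EngineConfig | None = None,
    *,
    with_se: bool = True,
) -> pd.DataFrame:
    """Long-format summary table: food, compound, statistic, value, SE.

    Rows cover food consumption (g/day; compound blank), per-(food, compound)
    intakes and whole-diet per-compound intakes (food ``(all)``), each with
    the configured statistic set.  With ``config.population == "consumers"``
    only subjects with a positive value for the row's quantity enter the
    summary; with ``"total"`` all subjects enter, zeros included.
    """
    config = config or EngineConfig()
    seeds = iter(np.random.SeedSequence(config.seed).spawn(10_000))
    rows: list[dict] = []

    def add(food: str, compound: str, unit: str, series: pd.Series) -> None:
        values, weights = _aligned(series, subjects)
        if config.population == "consumers":
            keep = values > 0
            if not keep.any():
                return
            values, weights = values[keep], weights[keep]
        if with_se:
            summary = bootstrap_summary(
                values, weights, config.statistics,
                B=config.bootstrap_reps, seed=next(seeds),
            )
        else:
            summary = weighted_summary(values, weights, config.statistics)
        for stat in config.statistics:
            rows.append(
                {
                    "food": food,
                    "compound": compound,
                    "unit": unit,
                    "statistic": stat,
                    "value": summary[stat],
                    "se": summary.standard_errors.get(stat, float("nan")),
                }
            )

    for plant, grp in result.food_consumption.groupby("plant", sort=True):
        add(str(plant), "", "g/day", grp.set_index("subject_id")["g_day"])
    for (plant, compound), grp in result.per_subject_food.groupby(
        ["plant", "compound"], sort=True
    ):
        add(str(plant), str(compound), "mg/day", grp.set_index("subject_id")["intake_mg_day"])
    for compound in result.compounds:
        add("(all)", str(compound), "mg/day", result.compound_intakes(compound))

    return pd.DataFrame(rows, columns=["food", "compound", "unit", "statistic", "value", "se"])
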