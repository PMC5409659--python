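"""End-to-end orchestration: files in, intake statistics out.

One assessment run reads the composition export, applies the refinement
filters, builds per-(plant, compound) concentration distributions, reads the
survey, maps and disaggregates consumed foods, simulates intakes, and
summarizes them with bootstrap SEs.  Scenario runs reuse the baseline's
concentration-draw substream, so inserting a fixed-dose product shifts
intakes without perturbing the baseline draws — dose comparisons are exact,
not confounded by fresh Monte Carlo noise.

All randomness flows from the single engine seed through fixed, named
substreams (intake draws, scenario adoption, bootstrap resampling).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import composition, engine, scenario, stats, survey
from .config import AssessmentConfig, ScenarioFileSpec
from .results import ResultStore

# Fixed substream keys; scenario adoption gets key (_SCENARIO, index).
_INTAKE, _SCENARIO, _BOOTSTRAP = 11, 31, 41


def _rng(seed, *keys) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(seed)] + [int(k) for k in keys]))


@dataclass
class AssessmentRun:
    subjects: pd.DataFrame  # with supplement_consumer flags
    events: pd.DataFrame
    mapped: survey.MappingResult
    distributions: dict
    intake: engine.IntakeResult
    store: ResultStore
    manifest: dict


def run_assessment(cfg: AssessmentConfig) -> AssessmentRun:
    """Execute the full baseline pipeline described by a config."""
    records, n_skipped = composition.read_concentration_export(
        cfg.composition, delimiter=cfg.delimiter, decimal=cfg.decimal
    )
    surviving = composition.filter_records(records, cfg.filters)
    distributions = composition.build_distributions(surviving)

    subjects, events = survey.read_survey(
        cfg.survey, delimiter=cfg.delimiter, n_days=cfg.survey_n_days
    )
    subjects = survey.flag_supplement_consumers(subjects, events)

    mapping = pd.read_csv(cfg.mapping, sep=cfg.delimiter)
    mapping_dict = dict(zip(mapping["food_code"].astype(str), mapping["plant_name"]))
    recipes = (
        pd.read_csv(cfg.recipes, sep=cfg.delimiter) if cfg.recipes is not None else ()
    )
    mapped = survey.map_events(events, mapping_dict, recipes)

    intake = engine.subject_daily_intakes(
        subjects, mapped.events, distributions, cfg.engine,
        rng=_rng(cfg.engine.seed, _INTAKE),
    )
    summary = engine.summarize_intakes(intake, subjects, cfg.engine)
    summary.insert(0, "dataset", cfg.dataset)
    store = ResultStore(summary)

    manifest = {
        "dataset": cfg.dataset,
        "seed": cfg.engine.seed,
        "iterations": cfg.engine.n_iterations,
        "bootstrap_reps": cfg.engine.bootstrap_reps,
        "draw_mode": cfg.engine.draw_mode,
        "population": cfg.engine.population,
        "records_read": len(records),
        "records_skipped_unparseable": n_skipped,
        "records_after_filtering": len(surviving),
        "filters": (
            f"exclude_parts={sorted(cfg.filters.exclude_parts)} "
            f"exclude_dry_weight={cfg.filters.exclude_dry_weight} "
            f"processing={cfg.filters.processing_match}"
        ),
        "n_subjects": len(subjects),
        "gram_coverage": round(mapped.gram_coverage, 6),
        "unmapped_codes": ",".join(mapped.unmapped_codes),
    }
    return AssessmentRun(subjects, events, mapped, distributions, intake, store, manifest)


def run_scenarios(
    cfg: AssessmentConfig,
    spec: ScenarioFileSpec | None,
    baseline: AssessmentRun | None = None,
) -> pd.DataFrame:
    """Baseline plus one row per (dose, probability): intake statistics table.

    Every row reports weighted mean/P25/median/P95 with bootstrap SEs, all on
    the same bootstrap resamples so rows are directly comparable.
    """
    base = baseline or run_assessment(cfg)
    seed = cfg.engine.seed
    stat_names = ("mean", "P25", "median", "P95")

    def summarize(result: engine.IntakeResult, label: str, prob) -> dict:
        values = (
            result.compound_intakes(spec.compound)
            .reindex(pd.Index(result.subject_order))
            .fillna(0.0)
            .to_numpy()
        )
        weights = base.subjects["survey_weight"].to_numpy(dtype=float)
        summary = stats.bootstrap_summary(
            values, weights, stat_names, B=cfg.engine.bootstrap_reps,
            seed=np.random.SeedSequence([int(seed), _BOOTSTRAP]),
        )
        row = {"scenario": label, "probability": prob}
        for s in stat_names:
            row[s] = summary[s]
            row[f"{s}_se"] = summary.standard_errors[s]
        return row

    rows = []
    if spec is None:
        # no scenario defined: baseline rows for every compound present
        for compound in base.intake.compounds:
            rows.append(summarize_baseline_compound(base, cfg, compound))
        return pd.DataFrame(rows)

    rows.append(summarize(base.intake, "baseline", None))
    run_index = 0
    for dose in spec.doses_mg:
        for p in spec.probabilities:
            run_index += 1
            sc = scenario.ScenarioSpec(
                compound=spec.compound,
                dose_mg=dose,
                events_per_day=spec.events_per_day,
                target_group=spec.target_group,
                consumption_probability=p,
                adoption_mode=spec.adoption_mode,
            )
            applied = scenario.apply_scenario(
                base.subjects, base.events, sc, _rng(seed, _SCENARIO, run_index)
            )
            # same intake substream as the baseline: identical concentration
            # draws, so the scenario differs only by the inserted doses
            result = engine.subject_daily_intakes(
                base.subjects, base.mapped.events, base.distributions, cfg.engine,
                rng=_rng(seed, _INTAKE), direct_doses=applied.direct_doses,
            )
            rows.append(summarize(result, f"capsule {dose:g} mg", p))
    columns = ["scenario", "probability"]
    for s in stat_names:
        columns += [s, f"{s}_se"]
    return pd.DataFrame(rows, columns=columns)


def summarize_baseline_compound(
    base: AssessmentRun, cfg: AssessmentConfig, compound: str
) -> dict:
    values = (
        base.intake.compound_intakes(compound)
        .reindex(pd.Index(base.intake.subject_order))
        .fillna(0.0)
        .to_numpy()
    )
    weights = base.subjects["survey_weight"].to_numpy(dtype=float)
    stat_names = ("mean", "P25", "median", "P95")
    summary = stats.bootstrap_summary(
        values, weights, stat_names, B=cfg.engine.bootstrap_reps,
        seed=np.random.SeedSequence([int(cfg.engine.seed), _BOOTSTRAP]),
    )
    row = {"scenario": f"baseline ({compound})", "probability": None}
    for s in stat_names:
        row[s] = summary[s]
        row[f"{s}_se"] = summary.standard_errors[s]
    return row
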