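"""Composition records: reading, filtering, unit harmonization, distributions.

A composition export is a delimited-text table of quality-coded analytical
measurements — one row per (plant, compound, publication) measurement, with
processing descriptors (part analysed, heat treatment, preservation method,
...) alongside the concentration itself.  This module reads such exports,
applies the refinements used when linking composition data to consumption
surveys (drop peel-only records, drop dry-weight records), converts all
surviving levels to mg per kg fresh weight, and groups them into discrete
per-(plant, compound) concentration distributions that the intake engine
samples from.  Records are deliberately *not* averaged: keeping every
analytical record lets the simulation propagate between-study variability.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Mandatory header fields of a composition export (case-insensitive match).
EXPORT_FIELDS = (
    "Scientific name",
    "Compound",
    "Level",
    "Unit",
    "Part",
    "Plant description",
    "Shape, state or form",
    "EuroFIR classification",
    "Heat treatment",
    "Cooking method",
    "Treatment applied",
    "Preservation method",
    "Quality code",
)

#: Optional columns; defaults applied when absent.
OPTIONAL_FIELDS = ("Plant name", "Compound class", "Reference")


@dataclass(frozen=True)
class ConcentrationRecord:
    """One quality-coded analytical measurement of a compound in a food."""

    plant_name: str
    scientific_name: str
    compound: str
    compound_class: str
    level: float
    unit: str
    part: str
    plant_description: str = ""
    shape_state_form: str = ""
    eurofir_classification: str = ""
    heat_treatment: str = ""
    cooking_method: str = ""
    treatment_applied: str = ""
    preservation_method: str = ""
    quality_code: str = ""
    reference_id: str = ""

    def __post_init__(self) -> None:
        if self.level < 0:
            raise ValueError(f"concentration level must be >= 0, got {self.level}")
        if not self.reference_id:
            raise ValueError("every record must carry a reference id")

    @property
    def unpublished(self) -> bool:
        """Unpublished data carry a distinguishing leading letter ('U')."""
        return self.reference_id[:1].upper() == "U"


# Descriptor values treated as "no processing" when matching raw foods.
_RAW_MARKERS = frozenset({"", "none", "raw", "not heated", "not cooked", "n/a", "fresh"})


@dataclass
class FilterRules:
    """Refinement rules applied before linking composition data to a survey.

    Defaults reproduce the standard refinements: peel-only records are not
    representative of the food as eaten, and dry-weight levels cannot be
    combined with fresh-weight consumption amounts without a moisture factor.
    ``processing_match`` selects which processing states survive, judged from
    the classification/treatment descriptor fields: ``"any"`` keeps all,
    ``"raw_only"`` keeps records with no processing descriptors set,
    ``"processed_only"`` keeps the complement.
    """

    exclude_parts: frozenset[str] = frozenset({"peel"})
    exclude_dry_weight: bool = True
    processing_match: str = "any"

    def __post_init__(self) -> None:
        self.exclude_parts = frozenset(p.strip().lower() for p in self.exclude_parts)
        if self.processing_match not in ("any", "raw_only", "processed_only"):
            raise ValueError(f"unknown processing policy {self.processing_match!r}")


@dataclass(frozen=True)
class ConcentrationDistribution:
    """Discrete set of harmonized concentrations (mg/kg) for one (plant, compound)."""

    plant_name: str
    compound: str
    values: np.ndarray  # mg/kg, one entry per surviving record
    record_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        if values.size == 0:
            raise ValueError("a concentration distribution may not be empty")
        if (values < 0).any():
            raise ValueError("concentrations must be >= 0")
        if len(self.record_ids) != values.size:
            raise ValueError("record_ids must parallel values")

    def __len__(self) -> int:
        return int(self.values.size)

    @property
    def mean(self) -> float:
        return float(self.values.mean())


class SchemaError(ValueError):
    """A delimited export is missing mandatory columns."""


class UnitError(ValueError):
    """A concentration unit cannot be converted to mg/kg fresh weight."""


def _canon(name: str) -> str:
    return re.sub(r"\s+", " ", name.strip().lower())


def read_concentration_export(
    path,
    *,
    delimiter: str = ",",
    decimal: str = ".",
) -> tuple[list[ConcentrationRecord], int]:
    """Read a composition export into records.

    Rows whose Level does not parse as a number (non-detects, "traces",
    "n.d.") are skipped; the skip count is returned and logged.  European
    exports using ``;`` as delimiter and ``,`` as decimal separator are
    supported through the keyword arguments.

    Returns
    -------
    (records, n_skipped)
    """
    frame = pd.read_csv(path, sep=delimiter, decimal=decimal, dtype=str, keep_default_na=False)
    colmap = {_canon(c): c for c in frame.columns}
    missing = [f for f in EXPORT_FIELDS if _canon(f) not in colmap]
    if missing:
        raise SchemaError(f"export {path} is missing mandatory columns: {', '.join(missing)}")

    def col(name: str, default: str = "") -> pd.Series:
        key = _canon(name)
        if key in colmap:
            return frame[colmap[key]].astype(str).str.strip()
        return pd.Series([default] * len(frame), index=frame.index)

    levels_raw = col("Level")
    if decimal != ".":
        levels_raw = levels_raw.str.replace(decimal, ".", regex=False)
    levels = pd.to_numeric(levels_raw, errors="coerce")

    plant = col("Plant name")
    scientific = col("Scientific name")
    plant = plant.where(plant != "", scientific)
    reference = col("Reference")

    records: list[ConcentrationRecord] = []
    n_skipped = 0
    for i, row in enumerate(frame.index):
        level = levels.loc[row]
        if not np.isfinite(level) or level < 0:
            n_skipped += 1
            continue
        ref = reference.loc[row] or f"R{i + 1}"
        records.append(
            ConcentrationRecord(
                plant_name=plant.loc[row],
                scientific_name=scientific.loc[row],
                compound=col("Compound").loc[row],
                compound_class=col("Compound class").loc[row],
                level=float(level),
                unit=col("Unit").loc[row],
                part=col("Part").loc[row],
                plant_description=col("Plant description").loc[row],
                shape_state_form=col("Shape, state or form").loc[row],
                eurofir_classification=col("EuroFIR classification").loc[row],
                heat_treatment=col("Heat treatment").loc[row],
                cooking_method=col("Cooking method").loc[row],
                treatment_applied=col("Treatment applied").loc[row],
                preservation_method=col("Preservation method").loc[row],
                quality_code=col("Quality code").loc[row],
                reference_id=ref,
            )
        )
    if n_skipped:
        logger.info("skipped %d rows with unparseable level in %s", n_skipped, path)
    return records, n_skipped


def _is_dry_weight(unit: str) -> bool:
    u = _canon(unit)
    return "dry weight" in u or u.endswith(" dw") or "/kg dw" in u


def _is_raw(record: ConcentrationRecord) -> bool:
    descriptors = (
        record.heat_treatment,
        record.cooking_method,
        record.treatment_applied,
        record.preservation_method,
    )
    return all(_canon(d) in _RAW_MARKERS for d in descriptors)


def filter_records(
    records: Sequence[ConcentrationRecord],
    rules: FilterRules | None = None,
) -> list[ConcentrationRecord]:
    """Apply refinement rules; order preserved, empty output legal (logged)."""
    rules = rules or FilterRules()
    out: list[ConcentrationRecord] = []
    for rec in records:
        if _canon(rec.part) in rules.exclude_parts:
            continue
        if rules.exclude_dry_weight and _is_dry_weight(rec.unit):
            continue
        if rules.processing_match == "raw_only" and not _is_raw(rec):
            continue
        if rules.processing_match == "processed_only" and _is_raw(rec):
            continue
        out.append(rec)
    if not out and records:
        logger.warning("filtering removed all %d records", len(records))
    return out


# Unit vocabulary -> factor multiplying the level to obtain mg/kg fresh weight.
_UNIT_FACTORS: dict[str, float] = {
    "mg/kg": 1.0,
    "mg/kg fresh weight": 1.0,
    "mg/kg fw": 1.0,
    "mg/100 g": 10.0,
    "mg/100g": 10.0,
    "mg/100 g fresh weight": 10.0,
    "mg/100g fresh weight": 10.0,
    "mg/100 g fw": 10.0,
    "µg/g": 1.0,
    "ug/g": 1.0,
    "µg/g fresh weight": 1.0,
    "ug/g fresh weight": 1.0,
}


def harmonize_unit(record: ConcentrationRecord) -> float:
    """Convert a record's level to mg/kg fresh weight.

    Dry-weight units are rejected (no moisture factor is available); such
    records must be removed by :func:`filter_records` first.
    """
    unit = _canon(record.unit)
    if _is_dry_weight(unit):
        raise UnitError(
            f"cannot convert dry-weight unit {record.unit!r} without a moisture factor"
        )
    try:
        factor = _UNIT_FACTORS[unit]
    except KeyError:
        raise UnitError(f"unit {record.unit!r} is outside the supported vocabulary") from None
    logger.debug("unit %r -> mg/kg, factor %g", record.unit, factor)
    return record.level * factor


def build_distributions(
    records: Sequence[ConcentrationRecord],
    plant_names: Iterable[str] | None = None,
) -> dict[tuple[str, str], ConcentrationDistribution]:
    """Group harmonized records into per-(plant, compound) discrete distributions.

    Every surviving record contributes one value — duplicates are kept and
    nothing is averaged, so sampling reflects the spread of the underlying
    analytical studies.  ``plant_names``, when given, restricts the output to
    those plants.
    """
    wanted = None if plant_names is None else {_canon(p) for p in plant_names}
    grouped: dict[tuple[str, str], tuple[list[float], list[str]]] = {}
    for rec in records:
        if wanted is not None and _canon(rec.plant_name) not in wanted:
            continue
        key = (rec.plant_name, rec.compound)
        values, ids = grouped.setdefault(key, ([], []))
        values.append(harmonize_unit(rec))
        ids.append(rec.reference_id)
    return {
        key: ConcentrationDistribution(
            plant_name=key[0], compound=key[1],
            values=np.asarray(vals), record_ids=tuple(ids),
        )
        for key, (vals, ids) in grouped.items()
    }


def distributions_to_frame(
    distributions: Mapping[tuple[str, str], ConcentrationDistribution],
) -> pd.DataFrame:
    """Long-format audit table: one row per (plant, compound, value, record id)."""
    rows = [
        {"plant": d.plant_name, "compound": d.compound,
         "concentration_mg_kg": float(v), "reference": r}
        for d in distributions.values()
        for v, r in zip(d.values, d.record_ids)
    ]
    return pd.DataFrame(rows, columns=["plant", "compound", "concentration_mg_kg", "reference"])
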