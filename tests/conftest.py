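"""Shared fixtures: small hand-built tables and a generated toy study."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from bioactive_intake import ConcentrationRecord

settings.register_profile("stable", derandomize=True, deadline=None)
settings.load_profile("stable")


def make_record(**kwargs) -> ConcentrationRecord:
    """A valid whole-fruit fresh-weight record with overridable fields."""
    defaults = dict(
        plant_name="Apple",
        scientific_name="Malus domestica",
        compound="Epicatechin",
        compound_class="Flavanols",
        level=147.0,
        unit="mg/kg",
        part="whole fruit",
        heat_treatment="none",
        cooking_method="none",
        treatment_applied="none",
        preservation_method="none",
        quality_code="A",
        reference_id="R001",
    )
    defaults.update(kwargs)
    return ConcentrationRecord(**defaults)


@pytest.fixture
def export_csv(tmp_path):
    """Write a composition export with the standard header; returns the path factory."""

    def write(rows: list[dict], name="comp.csv", drop_columns=(), delimiter=","):
        columns = [
            "Plant name", "Scientific name", "Compound", "Compound class", "Level",
            "Unit", "Part", "Plant description", "Shape, state or form",
            "EuroFIR classification", "Heat treatment", "Cooking method",
            "Treatment applied", "Preservation method", "Quality code", "Reference",
        ]
        frame = pd.DataFrame(rows)
        for col in columns:
            if col not in frame.columns:
                frame[col] = ""
        frame = frame[[c for c in columns if c not in drop_columns]]
        path = tmp_path / name
        frame.to_csv(path, index=False, sep=delimiter)
        return path

    return write


def export_row(**kwargs) -> dict:
    row = {
        "Plant name": "Apple",
        "Scientific name": "Malus domestica",
        "Compound": "Epicatechin",
        "Compound class": "Flavanols",
        "Level": 147.0,
        "Unit": "mg/kg",
        "Part": "whole fruit",
        "Heat treatment": "none",
        "Quality code": "A",
        "Reference": "R001",
    }
    row.update(kwargs)
    return row


@pytest.fixture
def two_subject_survey(tmp_path):
    """A 2-subject, 4-day diary file with weights and a supplement event."""
    rows = [
        ("A", 1.5, 1, "F-APPLE", 120.0, "Fruit"),
        ("A", 1.5, 2, "F-CHOC", 30.0, "Confectionery"),
        ("A", 1.5, 4, "F-APPLE", 80.0, "Fruit"),
        ("B", 0.5, 1, "F-APPLE", 100.0, "Fruit"),
        ("B", 0.5, 3, "SUPP-X", 1.0, "Dietary Supplements"),
        ("B", 0.5, 4, "F-TEA", 200.0, "Beverages"),
    ]
    frame = pd.DataFrame(
        rows, columns=["subject_id", "weight", "day", "food_code", "amount_g", "food_group"]
    )
    frame["n_days"] = 4
    path = tmp_path / "survey.csv"
    frame.to_csv(path, index=False)
    return path


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
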