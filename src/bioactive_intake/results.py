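"""Result storage and the exposure-style query facility.

Assessment output is a long-format table keyed by (dataset, food, compound,
statistic) with a value and a bootstrap SE — the same shape a
country/compound/food intake-statistics interface queries: pick a dataset,
a compound, a food and a statistic, get the number, its SE and a one-line
description, or a listing of what is available when the key is absent.
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from .stats import STATISTICS

KEY_COLUMNS = ["dataset", "food", "compound", "statistic"]
COLUMNS = KEY_COLUMNS + ["unit", "value", "se"]


class ResultNotFound(KeyError):
    """Query key absent; the message lists the nearest available options."""


@dataclass
class QueryResult:
    value: float
    se: float
    unit: str
    description: str


class ResultStore:
    """Long-format intake-statistics table with exact-match query."""

    def __init__(self, frame: pd.DataFrame):
        missing = [c for c in COLUMNS if c not in frame.columns]
        if missing:
            raise ValueError(f"result table is missing columns: {', '.join(missing)}")
        frame = frame.copy()
        # a blank compound marks a food-consumption (g/day) row; normalize the
        # NaN that CSV round-tripping produces back to the empty string
        frame["compound"] = frame["compound"].fillna("")
        bad = set(frame["statistic"]) - set(STATISTICS)
        if bad:
            raise ValueError(f"unknown statistics in result table: {sorted(bad)}")
        if frame.duplicated(KEY_COLUMNS).any():
            raise ValueError("result table keys must be unique")
        self._frame = frame[COLUMNS].reset_index(drop=True)

    @property
    def frame(self) -> pd.DataFrame:
        return self._frame.copy()

    def __len__(self) -> int:
        return len(self._frame)

    @classmethod
    def from_csv(cls, path) -> "ResultStore":
        return cls(pd.read_csv(path, comment="#"))

    def to_csv(self, path, *, provenance: dict | None = None) -> None:
        """Write the table with provenance recorded as leading comment lines."""
        buf = io.StringIO()
        for key, value in (provenance or {}).items():
            buf.write(f"# {key}: {value}\n")
        self._frame.to_csv(buf, index=False)
        Path(path).write_text(buf.getvalue())

    def options(self) -> dict[str, tuple]:
        return {
            col: tuple(sorted(self._frame[col].astype(str).unique()))
            for col in KEY_COLUMNS
        }

    def query(self, dataset: str, compound: str, food: str, statistic: str) -> QueryResult:
        """Exact-match lookup of one statistic with a one-line description."""
        if statistic not in STATISTICS:
            raise ValueError(
                f"statistic must be one of {', '.join(STATISTICS)}; got {statistic!r}"
            )
        f = self._frame
        hit = f[
            (f["dataset"] == dataset)
            & (f["compound"].fillna("") == compound)
            & (f["food"] == food)
            & (f["statistic"] == statistic)
        ]
        if not len(hit):
            opts = self.options()
            raise ResultNotFound(
                f"no result for dataset={dataset!r}, compound={compound!r}, "
                f"food={food!r}, statistic={statistic!r}; available datasets: "
                f"{opts['dataset']}; foods: {opts['food']}; compounds: {opts['compound']}"
            )
        row = hit.iloc[0]
        what = f"{compound} intake from {food}" if compound else f"{food} consumption"
        description = (
            f"{statistic} {what} in dataset {dataset}: "
            f"{row['value']:.4g} {row['unit']} (SE {row['se']:.3g})"
        )
        return QueryResult(
            value=float(row["value"]),
            se=float(row["se"]),
            unit=str(row["unit"]),
            description=description,
        )
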