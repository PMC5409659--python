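"""Survey-weighted summary statistics and subject-level bootstrap errors.

The population summaries reported by the intake model are weighted: each
subject contributes with their survey weight.  The weighted quantile is the
left-continuous inverse of the weighted empirical CDF — the smallest observed
value whose normalized cumulative weight (values sorted ascending) reaches
the requested level — which is well defined under arbitrary positive weights
and involves no interpolation, so results are exactly reproducible.

Standard errors come from a nonparametric bootstrap over *subjects*: subjects
are the independent sampling units of a diary survey, so each replicate
resamples n subjects with replacement, each carrying its weight, and the SE
of a statistic is the standard deviation of the statistic across replicates.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np

#: Statistics the model reports, in canonical order.
STATISTICS = ("mean", "P25", "median", "P95", "min", "max")

_QUANTILE_OF = {"P25": 0.25, "median": 0.5, "P95": 0.95}


def weighted_mean(values, weights) -> float:
    values = np.asarray(values, dtype=float)
    weights = np.asarray(weights, dtype=float)
    return float(np.sum(weights * values) / np.sum(weights))


def weighted_quantile(values, weights, q: float) -> float:
    """Smallest x with normalized cumulative weight >= q (values ascending)."""
    if not 0 <= q <= 1:
        raise ValueError("quantile level must be in [0, 1]")
    values = np.asarray(values, dtype=float)
    weights = np.asarray(weights, dtype=float)
    if values.size == 0:
        raise ValueError("cannot take a quantile of an empty sample")
    order = np.argsort(values, kind="stable")
    values, weights = values[order], weights[order]
    cum = np.cumsum(weights) / np.sum(weights)
    idx = int(np.searchsorted(cum, q, side="left"))
    return float(values[min(idx, values.size - 1)])


def _one_statistic(name: str) -> Callable[[np.ndarray, np.ndarray], float]:
    if name == "mean":
        return weighted_mean
    if name in _QUANTILE_OF:
        q = _QUANTILE_OF[name]
        return lambda v, w: weighted_quantile(v, w, q)
    if name == "min":
        return lambda v, w: float(np.min(v))
    if name == "max":
        return lambda v, w: float(np.max(v))
    raise ValueError(f"unknown statistic {name!r}; choose from {STATISTICS}")


@dataclass
class SummaryStatistics:
    """Weighted population summary, optionally with bootstrap standard errors."""

    values: dict[str, float]
    standard_errors: dict[str, float] = field(default_factory=dict)
    n: int = 0

    def __post_init__(self) -> None:
        order = [s for s in ("min", "P25", "median", "P95", "max") if s in self.values]
        seq = [self.values[s] for s in order]
        if any(a > b + 1e-12 for a, b in zip(seq, seq[1:])):
            raise ValueError(f"order statistics are not monotone: {self.values}")
        if any(se < 0 for se in self.standard_errors.values()):
            raise ValueError("standard errors must be >= 0")

    def __getitem__(self, statistic: str) -> float:
        return self.values[statistic]


def weighted_summary(
    values,
    weights=None,
    statistics: Sequence[str] = STATISTICS,
) -> SummaryStatistics:
    """Compute the weighted statistic set over per-subject values."""
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("cannot summarize an empty sample")
    weights = np.ones_like(values) if weights is None else np.asarray(weights, dtype=float)
    if weights.shape != values.shape:
        raise ValueError("weights must have the same length as values")
    if (weights <= 0).any():
        raise ValueError("weights must be strictly positive")
    out = {name: _one_statistic(name)(values, weights) for name in statistics}
    return SummaryStatistics(values=out, n=int(values.size))


def bootstrap_se(
    values,
    weights=None,
    statistic: str = "mean",
    B: int = 1000,
    seed=None,
) -> float:
    """Bootstrap SE of one weighted statistic (resampling subjects)."""
    return bootstrap_summary(values, weights, [statistic], B=B, seed=seed).standard_errors[
        statistic
    ]


def bootstrap_summary(
    values,
    weights=None,
    statistics: Sequence[str] = STATISTICS,
    B: int = 1000,
    seed=None,
) -> SummaryStatistics:
    """Weighted summary with bootstrap SEs for every requested statistic.

    One set of B subject resamples serves all statistics, so SEs across
    statistics are computed on the same replicates.  ``seed`` accepts anything
    :func:`numpy.random.default_rng` does; the same seed reproduces the SEs
    bit for bit.
    """
    if B < 2:
        raise ValueError("bootstrap needs at least 2 replicates")
    values = np.asarray(values, dtype=float)
    n = values.size
    weights = np.ones(n) if weights is None else np.asarray(weights, dtype=float)
    point = weighted_summary(values, weights, statistics)

    rng = np.random.default_rng(seed)
    funcs = {name: _one_statistic(name) for name in statistics}
    replicates = {name: np.empty(B) for name in statistics}
    for b in range(B):
        idx = rng.integers(0, n, size=n)
        v, w = values[idx], weights[idx]
        for name, fn in funcs.items():
            replicates[name][b] = fn(v, w)
    point.standard_errors = {
        name: float(np.std(reps, ddof=1)) for name, reps in replicates.items()
    }
    return point
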