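"""Per-animal daily gas-flux estimation from spot samples.

A daily flux estimate for one animal is an average over its qualifying
visits.  Two averaging methods are provided:

* ``arithmetic`` — plain mean over qualifying visits;
* ``time_bin`` — visits are grouped into clock-time bins (default eight
  3-h bins), the within-bin means are computed, and the estimate is the
  unweighted mean over occupied bins, which weights the day uniformly when
  visitation is diurnally uneven.

Qualifying visits are selected with a :class:`DurationRule`, either a
minimum-duration threshold (e.g. >=3 min) or a half-open range
(e.g. >=1 and <2 min).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ahcsflux.io import GAS_COLUMNS, VisitTable


@dataclass(frozen=True)
class DurationRule:
    """Half-open visit-duration selector ``lower <= duration < upper`` (min)."""

    lower: float
    upper: float = math.inf

    def __post_init__(self) -> None:
        if not self.lower < self.upper:
            raise ValueError("duration rule requires lower < upper")
        if self.lower < 0:
            raise ValueError("duration lower bound must be >= 0")

    @classmethod
    def threshold(cls, minutes: float) -> "DurationRule":
        """Minimum-duration rule: keep visits >= ``minutes``."""
        return cls(lower=minutes)

    @classmethod
    def range(cls, lower: float, upper: float) -> "DurationRule":
        """Range rule: keep visits with lower <= duration < upper."""
        return cls(lower=lower, upper=upper)

    @classmethod
    def all_visits(cls) -> "DurationRule":
        return cls(lower=0.0)

    @property
    def kind(self) -> str:
        return "threshold" if math.isinf(self.upper) else "range"

    @property
    def label(self) -> str:
        if self.lower == 0 and math.isinf(self.upper):
            return "all"
        if math.isinf(self.upper):
            return f">={self.lower:g}min"
        return f"[{self.lower:g},{self.upper:g})min"

    def qualifies(self, duration_min: pd.Series | np.ndarray) -> np.ndarray:
        d = np.asarray(duration_min, dtype=float)
        return (d >= self.lower) & (d < self.upper)


#: the four threshold rules compared throughout: >=3, >=2, >=1 min, all visits
DEFAULT_THRESHOLDS = (
    DurationRule.threshold(3),
    DurationRule.threshold(2),
    DurationRule.threshold(1),
    DurationRule.all_visits(),
)

#: gold standard selector: all visits >= 3 min
GOLD_RULE = DurationRule.threshold(3)

#: the seven disjoint duration ranges used for stratified reports
DEFAULT_RANGES = (
    DurationRule.range(0, 1),
    DurationRule.range(1, 2),
    DurationRule.range(2, 3),
    DurationRule.range(3, 4),
    DurationRule.range(4, 5),
    DurationRule.range(5, 6),
    DurationRule.threshold(6),
)


@dataclass(frozen=True)
class TimeBinScheme:
    """Partition of the 24-h clock into half-open hour bins."""

    boundaries: tuple[float, ...] = (0, 3, 6, 9, 12, 15, 18, 21, 24)

    def __post_init__(self) -> None:
        b = self.boundaries
        if b[0] != 0 or b[-1] != 24 or any(x >= y for x, y in zip(b, b[1:])):
            raise ValueError("bin boundaries must increase from 0 to 24")

    @property
    def n_bins(self) -> int:
        return len(self.boundaries) - 1

    def assign(self, start_time: pd.Series) -> np.ndarray:
        """Bin index for each visit by its start-time clock hour."""
        hours = (
            start_time.dt.hour
            + start_time.dt.minute / 60
            + start_time.dt.second / 3600
        ).to_numpy()
        return np.digitize(hours, self.boundaries[1:-1])


def _gas_column(gas: str) -> str:
    try:
        return GAS_COLUMNS[gas]
    except KeyError:
        raise ValueError(f"unknown gas {gas!r}; expected one of {list(GAS_COLUMNS)}") from None


def arithmetic_estimates(
    table: VisitTable, gas: str, rule: DurationRule
) -> pd.DataFrame:
    """Arithmetic-mean daily flux per animal over qualifying visits.

    Animals with zero qualifying visits (or all-missing gas values) are
    omitted.  Returns a frame with columns ``animal_id``, ``gas``,
    ``estimate``, ``n_visits``, ``rule``, ``method``.
    """
    col = _gas_column(gas)
    df = table.df
    mask = rule.qualifies(df["duration_min"]) & df[col].notna().to_numpy()
    sub = df.loc[mask]
    g = sub.groupby("animal_id", observed=True)[col]
    out = pd.DataFrame({"estimate": g.mean(), "n_visits": g.size()})
    out = out.reset_index()
    out["gas"] = gas
    out["rule"] = rule.label
    out["method"] = "arithmetic"
    return out[["animal_id", "gas", "estimate", "n_visits", "rule", "method"]]


def time_bin_estimates(
    table: VisitTable,
    gas: str,
    rule: DurationRule,
    scheme: TimeBinScheme | None = None,
) -> pd.DataFrame:
    """Time-bin-averaged daily flux per animal.

    Qualifying visits are assigned to bins by start-time clock hour; the
    estimate is the unweighted mean of the occupied bins' means (empty bins
    are excluded rather than imputed).  ``n_bins_occupied`` is reported so
    users can screen animals with sparse day coverage.
    """
    scheme = scheme or TimeBinScheme()
    col = _gas_column(gas)
    df = table.df
    mask = rule.qualifies(df["duration_min"]) & df[col].notna().to_numpy()
    sub = df.loc[mask].copy()
    sub["_bin"] = scheme.assign(sub["start_time"])
    bin_means = sub.groupby(["animal_id", "_bin"], observed=True)[col].mean()
    g = bin_means.groupby("animal_id", observed=True)
    out = pd.DataFrame(
        {
            "estimate": g.mean(),
            "n_bins_occupied": g.size(),
            "n_visits": sub.groupby("animal_id", observed=True).size(),
        }
    ).reset_index()
    out["gas"] = gas
    out["rule"] = rule.label
    out["method"] = "time_bin"
    return out[
        ["animal_id", "gas", "estimate", "n_visits", "n_bins_occupied", "rule", "method"]
    ]


def method_difference(a: pd.DataFrame, b: pd.DataFrame) -> tuple[float, float]:
    """Mean signed difference between two estimate sets, paired by animal.

    Returns ``(mean(a - b) in g/d, that mean as % of mean(b))``.  Signed,
    not absolute, so opposite per-animal deviations can cancel.
    """
    merged = a.merge(b, on="animal_id", suffixes=("_a", "_b"))
    if merged.empty:
        raise ValueError("no animals in common between the two estimate sets")
    diff = float((merged["estimate_a"] - merged["estimate_b"]).mean())
    base = float(merged["estimate_b"].mean())
    return diff, 100.0 * diff / base
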