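"""Threshold and duration-range report tables, derived percentages and
study-length arithmetic.

Two stratified reports are produced from a QC-filtered visit table:

* by duration *threshold* (>=3, >=2, >=1 min, all visits) — descriptive
  statistics per experiment and agreement of each relaxed threshold with
  the >=3-min gold standard, per experiment and pooled;
* by duration *range* (seven disjoint ranges partitioning the visits) —
  descriptive statistics and agreement of each range's estimates with the
  gold standard.

Cross-experiment derived percentages (how much a relaxed threshold inflates
visit numbers, how far each range's flux estimates sit from the gold
standard) and the study-days arithmetic ("how long must a trial run to bank
n qualifying visits per animal") operate on summary values and therefore
work equally on computed reports and on published summary tables
(:mod:`ahcsflux.published`).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ahcsflux import published
from ahcsflux.agreement import AgreementStats, compare_estimates
from ahcsflux.estimation import (
    DEFAULT_RANGES,
    DEFAULT_THRESHOLDS,
    GOLD_RULE,
    DurationRule,
    arithmetic_estimates,
)
from ahcsflux.io import GASES, VisitTable, per_animal_summary


def _experiment_tables(table: VisitTable) -> dict[str, VisitTable]:
    return {
        exp: table.select((table.df["experiment_id"] == exp).to_numpy(), f"experiment {exp}")
        for exp in table.df["experiment_id"].unique()
    }


def descriptive_by_threshold(
    table: VisitTable, rules: tuple[DurationRule, ...] = DEFAULT_THRESHOLDS
) -> pd.DataFrame:
    """Cross-animal mean +/- SD of visit behaviour and flux, per experiment
    and duration threshold.

    SD is the between-animal SD of per-animal values.  Cells with no
    qualifying visits are omitted; a single-animal cell reports SD as NaN.
    Tidy output: ``experiment, rule, item, mean, sd, n_animals``.
    """
    rows = []
    for exp, sub in _experiment_tables(table).items():
        for rule in rules:
            qual = sub.select(rule.qualifies(sub.df["duration_min"]), rule.label)
            if len(qual) == 0:
                continue
            summ = per_animal_summary(qual)
            items = {
                "duration": summ["duration_mean"],
                "visits_per_day": summ["visits_per_day"],
                "n_visits": summ["n_visits"].astype(float),
            }
            for gas in GASES:
                est = arithmetic_estimates(qual, gas, DurationRule.all_visits())
                items[gas] = est.set_index("animal_id")["estimate"]
            for item, vals in items.items():
                rows.append(
                    {
                        "experiment": exp,
                        "rule": rule.label,
                        "item": item,
                        "mean": float(vals.mean()),
                        "sd": float(vals.std(ddof=1)) if len(vals) > 1 else float("nan"),
                        "n_animals": int(len(vals)),
                    }
                )
    return pd.DataFrame(rows)


def _stats_row(stats: AgreementStats | None, note: str | None = None) -> dict:
    if stats is None:
        return {"r": np.nan, "cb": np.nan, "ccc": np.nan, "rmse_pct": np.nan,
                "n_pairs": 0, "note": note}
    return {"r": stats.r, "cb": stats.cb, "ccc": stats.ccc,
            "rmse_pct": stats.rmse_pct, "n_pairs": stats.n_pairs, "note": ""}


def agreement_by_threshold(
    table: VisitTable,
    rules: tuple[DurationRule, ...] = DEFAULT_THRESHOLDS,
    pooled: bool = True,
) -> pd.DataFrame:
    """Agreement of each threshold's estimates with the >=3-min gold standard.

    Per experiment, each candidate rule's per-animal arithmetic estimates
    are compared with the same experiment's gold estimates.  With
    ``pooled=True`` an additional ``experiment='pooled'`` block concatenates
    all experiments' animal-level pairs into one unweighted comparison.
    Cells with fewer than 3 pairable animals are reported with a note.
    """
    rows = []
    per_exp = _experiment_tables(table)
    for gas in GASES:
        pooled_pairs: dict[str, list[pd.DataFrame]] = {r.label: [] for r in rules}
        for exp, sub in per_exp.items():
            gold = arithmetic_estimates(sub, gas, GOLD_RULE)
            for rule in rules:
                cand = arithmetic_estimates(sub, gas, rule)
                pooled_pairs[rule.label].append((cand, gold))
                try:
                    stats = compare_estimates(cand, gold)
                    row = _stats_row(stats)
                except ValueError as exc:
                    row = _stats_row(None, note=str(exc))
                rows.append({"experiment": exp, "gas": gas, "rule": rule.label, **row})
        if pooled:
            for rule in rules:
                cands = pd.concat([c for c, _ in pooled_pairs[rule.label]])
                golds = pd.concat([g for _, g in pooled_pairs[rule.label]])
                try:
                    stats = compare_estimates(cands, golds)
                    row = _stats_row(stats)
                except ValueError as exc:
                    row = _stats_row(None, note=str(exc))
                rows.append({"experiment": "pooled", "gas": gas, "rule": rule.label, **row})
    return pd.DataFrame(rows)


def duration_range_report(
    table: VisitTable, ranges: tuple[DurationRule, ...] = DEFAULT_RANGES
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Descriptive and agreement reports stratified by duration range.

    Pooled across experiments (the ranges partition the visit multiset).
    Returns ``(descriptive, agreement)`` frames.  Descriptive: per range,
    the number of animals represented, visits per animal, duration and
    per-gas per-animal means, summarised cross-animal as mean +/- SD.
    Agreement: each range's per-animal estimates vs the gold standard (all
    >=3-min visits); ranges with fewer than 3 pairable animals carry a note.
    """
    desc_rows, agree_rows = [], []
    gold = {gas: arithmetic_estimates(table, gas, GOLD_RULE) for gas in GASES}
    for rule in ranges:
        qual = table.select(rule.qualifies(table.df["duration_min"]), rule.label)
        if len(qual) == 0:
            desc_rows.append({"rule": rule.label, "n_animals": 0})
            continue
        summ = per_animal_summary(qual)
        row = {
            "rule": rule.label,
            "n_animals": int(len(summ)),
            "visits_mean": float(summ["n_visits"].mean()),
            "visits_sd": float(summ["n_visits"].std(ddof=1)),
            "duration_mean": float(summ["duration_mean"].mean()),
            "duration_sd": float(summ["duration_mean"].std(ddof=1)),
        }
        for gas in GASES:
            est = arithmetic_estimates(qual, gas, DurationRule.all_visits())
            row[f"{gas}_mean"] = float(est["estimate"].mean())
            row[f"{gas}_sd"] = float(est["estimate"].std(ddof=1))
            try:
                stats = compare_estimates(est, gold[gas])
                arow = _stats_row(stats)
            except ValueError as exc:
                arow = _stats_row(None, note=str(exc))
            agree_rows.append({"rule": rule.label, "gas": gas, **arow})
        desc_rows.append(row)
    return pd.DataFrame(desc_rows), pd.DataFrame(agree_rows)


def percent_difference_summary(
    values: pd.Series, reference: pd.Series
) -> tuple[pd.Series, float]:
    """Signed percent difference per group, and the unweighted cross-group mean.

    ``percent = (value - reference) / reference * 100`` per group (groups
    aligned by index, e.g. experiments or duration ranges), then an
    unweighted mean across groups.  Applies to visit counts as well as to
    gas means.
    """
    values, reference = values.align(reference, join="inner")
    if len(values) == 0:
        raise ValueError("no common groups between values and reference")
    if (reference == 0).any():
        raise ValueError("zero reference value")
    pct = (values - reference) / reference * 100.0
    return pct, float(pct.mean())


@dataclass(frozen=True)
class StudyDays:
    """Days of data collection needed to bank ``n_required`` visits."""

    raw: float
    days: int  # rounded up to whole days


def study_days_required(n_required: int, visits_per_day: float) -> StudyDays:
    """Study length needed for ``n_required`` qualifying visits per animal
    at an observed qualifying-visit rate (visits/day)."""
    if not visits_per_day > 0:
        raise ValueError("visits_per_day must be positive")
    raw = n_required / visits_per_day
    return StudyDays(raw=raw, days=math.ceil(raw))


# ---------------------------------------------------------------------------
# Derived summaries over the published per-experiment tables
# ---------------------------------------------------------------------------

def published_threshold_percentages() -> dict[str, float]:
    """Cross-experiment percentages derived from the published
    threshold-stratified summaries.

    ``visits_gain_pct_*``: how much relaxing the threshold from >=3 min
    inflates the number of visits per animal (mean over experiments).
    ``{gas}_ge3_vs_all_pct``: how much greater the >=3-min flux estimate is
    than the all-visits estimate (all-visits mean as base).
    """
    out: dict[str, float] = {}
    v3 = published.item_by_experiment("n_visits", ">=3min")
    for rule, key in ((">=2min", "ge2min"), (">=1min", "ge1min"), ("all", "all")):
        _, mean_pct = percent_difference_summary(
            published.item_by_experiment("n_visits", rule), v3
        )
        out[f"visits_gain_pct_{key}"] = mean_pct
    for gas in GASES:
        _, mean_pct = percent_difference_summary(
            published.item_by_experiment(gas, ">=3min"),
            published.item_by_experiment(gas, "all"),
        )
        out[f"{gas}_ge3_vs_all_pct"] = mean_pct
    return out


def published_range_percentages() -> dict[str, float]:
    """Per-range flux shortfall/excess vs the >=3-min gold standard, from the
    published pooled range summaries (gold mean as base)."""
    rs = published.range_summary().set_index("rule")
    out: dict[str, float] = {}
    keys = {
        "[0,1)min": "lt1min",
        "[1,2)min": "1to2min",
        "[2,3)min": "2to3min",
        "[3,4)min": "3to4min",
    }
    for gas in GASES:
        gold = rs.loc[">=3min", f"{gas}_mean"]
        for rule, key in keys.items():
            out[f"{gas}_range_{key}_pct"] = float(
                (rs.loc[rule, f"{gas}_mean"] - gold) / gold * 100.0
            )
    return out


def published_study_days() -> dict[str, float]:
    """Study-length arithmetic at the published qualifying-visit rates.

    Headline numbers: days to bank 30 visits >= 3 min at grazing and
    feedlot visit rates, days to bank 40 visits >= 2 min at the feedlot
    rate, and the mean percent increase in study days when moving from the
    (30 visits, >=3 min) design to the (40 visits, >=2 min) design across
    the four experiments.
    """
    r3 = published.item_by_experiment("visits_per_day", ">=3min")
    r2 = published.item_by_experiment("visits_per_day", ">=2min")
    days3 = {exp: study_days_required(30, r) for exp, r in r3.items()}
    days2 = {exp: study_days_required(40, r) for exp, r in r2.items()}
    extra = np.mean(
        [(days2[e].raw - days3[e].raw) / days3[e].raw * 100.0 for e in r3.index]
    )
    return {
        "study_days_30visits_grazing_a": days3["grazing_a"].days,
        "study_days_30visits_feedlot": days3["feedlot"].days,
        "study_days_40visits_ge2_feedlot": days2["feedlot"].days,
        "extra_days_pct_ge2_design": float(extra),
    }
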