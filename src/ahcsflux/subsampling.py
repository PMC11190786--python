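"""Random visit-subsampling experiment: how many visits per animal are enough?

For each duration threshold (>=3, >=2, >=1 min) and each visit count n on a
grid (default 5..60 by 5), draw n qualifying visits per animal at random
without replacement, form per-animal arithmetic estimates, and measure
agreement with the gold standard — each animal's mean over ALL of its
>=3-min QC-passed visits, which is never subsampled.  The minimum adequate
number of visits per (gas x threshold) is the smallest n whose
replicate-mean CCC reaches the excellent-agreement cut (default 0.90).

Animals must support the largest n in the grid (eligibility default =
max(n_grid)) so the compared animal set is constant across the grid.
Within a replicate the subsets are nested across n (each animal's
qualifying visits are permuted once per replicate and the first n are
taken), so every subset is a uniform simple random sample and the CCC
curves across n share common random numbers.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ahcsflux.agreement import ccc_matrix
from ahcsflux.estimation import GOLD_RULE, DurationRule
from ahcsflux.io import GAS_COLUMNS, VisitTable

_GAS_ORDER = ("co2", "o2", "ch4")


@dataclass(frozen=True)
class SubsamplingDesign:
    """Design of the subsampling grid.

    ``replicates=1`` (or ``single_draw=True``) mimics a single random draw
    per cell; the default of 100 replicates stabilises the CCC-vs-n curves.
    """

    thresholds: tuple[DurationRule, ...] = (
        DurationRule.threshold(3),
        DurationRule.threshold(2),
        DurationRule.threshold(1),
    )
    n_grid: tuple[int, ...] = tuple(range(5, 61, 5))
    replicates: int = 100
    seed: int = 0
    eligibility: int | None = None  # min qualifying visits; None -> max(n_grid)
    ccc_cut: float = 0.90
    single_draw: bool = False
    # compare all thresholds on the animals eligible under every threshold
    # (the qualifying sets are nested, so this is the strictest threshold's
    # set); otherwise each threshold uses its own eligible set and the
    # cross-threshold comparison confounds threshold with cohort composition
    common_animals: bool = True

    def __post_init__(self) -> None:
        if any(b <= a for a, b in zip(self.n_grid, self.n_grid[1:])) or min(self.n_grid) < 2:
            raise ValueError("n_grid must be strictly increasing with all entries >= 2")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")

    @property
    def n_replicates(self) -> int:
        return 1 if self.single_draw else self.replicates

    @property
    def min_eligible(self) -> int:
        return max(self.n_grid) if self.eligibility is None else self.eligibility


@dataclass
class SubsamplingResult:
    """Grid of agreement statistics plus the per-cell mean estimates.

    ``cells`` is long-format: one row per (gas, threshold, n, replicate)
    with r, Cb, ccc, rmse_pct, n_pairs and the cross-animal mean candidate
    estimate.  ``gold`` holds the per-animal gold-standard estimates (one
    row per gas x animal), identical across all cells.  ``eligible`` maps
    threshold label -> the animal ids used.
    """

    design: SubsamplingDesign
    cells: pd.DataFrame
    gold: pd.DataFrame
    eligible: dict[str, list[str]] = field(default_factory=dict)


def _qualifying(table: VisitTable, threshold: DurationRule) -> pd.DataFrame:
    mask = threshold.qualifies(table.df["duration_min"])
    return table.df.loc[mask]


def eligible_animals(
    table: VisitTable, threshold: DurationRule, min_visits: int
) -> list[str]:
    """Animals with at least ``min_visits`` visits qualifying under ``threshold``."""
    counts = _qualifying(table, threshold).groupby("animal_id", observed=True).size()
    return sorted(counts.index[counts >= min_visits])


def subsample_estimates(
    table: VisitTable,
    threshold: DurationRule,
    n: int,
    rng: np.random.Generator,
    animals: list[str] | None = None,
) -> pd.DataFrame:
    """Per-animal estimates from n randomly drawn qualifying visits.

    The draw is uniform without replacement.  Every included animal must
    have at least n qualifying visits.  Returns one row per animal x gas
    with columns ``animal_id, gas, estimate, n_visits, rule, method``.
    """
    qual = _qualifying(table, threshold)
    rows = []
    for animal, grp in qual.groupby("animal_id", observed=True):
        if animals is not None and animal not in animals:
            continue
        m = len(grp)
        if m < n:
            raise ValueError(
                f"animal {animal!r} has only {m} qualifying visits (< n={n})"
            )
        pick = rng.choice(m, size=n, replace=False)
        sub = grp.iloc[pick]
        for gas in _GAS_ORDER:
            rows.append(
                {
                    "animal_id": animal,
                    "gas": gas,
                    "estimate": float(sub[GAS_COLUMNS[gas]].mean()),
                    "n_visits": n,
                    "rule": threshold.label,
                    "method": "arithmetic",
                }
            )
    return pd.DataFrame(rows)


def run_grid(table: VisitTable, design: SubsamplingDesign) -> SubsamplingResult:
    """Evaluate the full (threshold x n x replicate) grid.

    The gold standard (per-animal mean of all >=3-min visits) is computed
    once and reused in every cell.  Per replicate and animal, the
    qualifying visits are permuted with a stream spawned from the design
    seed, and prefix means provide the estimates for every n at once.
    """
    golds = {}
    gold_df_rows = []
    df3 = _qualifying(table, GOLD_RULE)
    gold_by_animal = df3.groupby("animal_id", observed=True)[
        [GAS_COLUMNS[g] for g in _GAS_ORDER]
    ].mean()
    for gas in _GAS_ORDER:
        golds[gas] = gold_by_animal[GAS_COLUMNS[gas]]
        for animal, val in golds[gas].items():
            gold_df_rows.append(
                {"animal_id": animal, "gas": gas, "estimate": float(val),
                 "rule": GOLD_RULE.label, "method": "arithmetic"}
            )

    n_grid = np.asarray(design.n_grid)
    reps = design.n_replicates
    records = []
    eligible_map: dict[str, list[str]] = {}
    common: set[str] | None = None
    if design.common_animals:
        for threshold in design.thresholds:
            elig = set(eligible_animals(table, threshold, design.min_eligible))
            common = elig if common is None else common & elig
    for t_idx, threshold in enumerate(design.thresholds):
        animals = eligible_animals(table, threshold, design.min_eligible)
        if common is not None:
            animals = [a for a in animals if a in common]
        animals = [a for a in animals if a in gold_by_animal.index]
        eligible_map[threshold.label] = animals
        if len(animals) < 3:
            raise ValueError(
                f"fewer than 3 eligible animals under {threshold.label} "
                f"(need >= {design.min_eligible} qualifying visits)"
            )
        qual = _qualifying(table, threshold)
        rng = np.random.default_rng(
            np.random.SeedSequence(entropy=design.seed, spawn_key=(t_idx,))
        )
        max_n = int(n_grid.max())
        # prefix-mean estimates: (reps, len(n_grid), n_animals, 3 gases)
        est = np.empty((reps, len(n_grid), len(animals), 3))
        for a_idx, animal in enumerate(animals):
            vals = qual.loc[
                qual["animal_id"] == animal, [GAS_COLUMNS[g] for g in _GAS_ORDER]
            ].to_numpy()
            order = np.argsort(rng.random((reps, len(vals))), axis=1)[:, :max_n]
            picked = vals[order]  # (reps, max_n, 3)
            csum = np.cumsum(picked, axis=1)
            est[:, :, a_idx, :] = csum[:, n_grid - 1, :] / n_grid[None, :, None]
        for g_idx, gas in enumerate(_GAS_ORDER):
            gold_vec = golds[gas].loc[animals].to_numpy()
            stats = ccc_matrix(est[:, :, :, g_idx], gold_vec)
            mean_est = est[:, :, :, g_idx].mean(axis=-1)
            for r_idx in range(reps):
                for n_idx, n in enumerate(n_grid):
                    records.append(
                        {
                            "gas": gas,
                            "threshold": threshold.label,
                            "n": int(n),
                            "replicate": r_idx,
                            "r": float(stats["r"][r_idx, n_idx]),
                            "cb": float(stats["cb"][r_idx, n_idx]),
                            "ccc": float(stats["ccc"][r_idx, n_idx]),
                            "rmse_pct": float(stats["rmse_pct"][r_idx, n_idx]),
                            "n_pairs": len(animals),
                            "mean_estimate": float(mean_est[r_idx, n_idx]),
                        }
                    )
    return SubsamplingResult(
        design=design,
        cells=pd.DataFrame(records),
        gold=pd.DataFrame(gold_df_rows),
        eligible=eligible_map,
    )


def minimum_visits(
    result: SubsamplingResult, ccc_cut: float | None = None
) -> pd.DataFrame:
    """Minimum n per (gas x threshold) whose replicate-mean CCC reaches the cut.

    First-crossing rule: the smallest grid n with mean CCC >= cut, even if
    a larger n dips back below (such non-monotone curves are flagged).
    ``n_min`` is NaN (reported as "not reached") when no grid n qualifies.
    """
    cut = result.design.ccc_cut if ccc_cut is None else ccc_cut
    rows = []
    mean_ccc = (
        result.cells.groupby(["gas", "threshold", "n"], observed=True)["ccc"]
        .mean()
        .reset_index()
    )
    for (gas, thr), grp in mean_ccc.groupby(["gas", "threshold"], observed=True):
        grp = grp.sort_values("n")
        passing = grp.loc[grp["ccc"] >= cut, "n"]
        n_min = float(passing.iloc[0]) if len(passing) else float("nan")
        monotone = bool((np.diff(grp["ccc"]) >= -1e-12).all())
        rows.append(
            {
                "gas": gas,
                "threshold": thr,
                "n_min": n_min,
                "reached": bool(len(passing)),
                "monotone": monotone,
                "max_mean_ccc": float(grp["ccc"].max()),
            }
        )
    return pd.DataFrame(rows)
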