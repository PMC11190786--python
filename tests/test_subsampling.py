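import numpy as np
import pandas as pd
import pytest

from ahcsflux.estimation import DurationRule, arithmetic_estimates
from ahcsflux.qc import run_qc
from ahcsflux.simulate import SyntheticCohortConfig, generate_cohort
from ahcsflux.subsampling import (
    SubsamplingDesign,
    SubsamplingResult,
    eligible_animals,
    minimum_visits,
    run_grid,
    subsample_estimates,
)
from tests.conftest import build_table, clean_row


def _uniform_table(n_animals=5, n_visits=60, rng_seed=0):
    """Animals with exactly n_visits qualifying (>=3 min) visits each."""
    rng = np.random.default_rng(rng_seed)
    rows = []
    for a in range(n_animals):
        base = 120.0 + 20.0 * a
        for v in range(n_visits):
            rows.append(
                clean_row(
                    f"A{a}",
                    start=f"2023-01-{1 + v // 4:02d}T{(v % 4) * 6:02d}:30:00",
                    duration=3.5,
                    ch4=base + rng.normal(0, 5),
                    co2=40 * base + rng.normal(0, 100),
                    o2=30 * base + rng.normal(0, 80),
                )
            )
    return build_table(rows)


class TestEligibility:
    def test_threshold_counts(self):
        table = _uniform_table(n_animals=2, n_visits=60)
        # drop one visit from A1 -> 59 qualifying
        keep = ~((table.df["animal_id"] == "A1") & (table.df.index == len(table.df) - 1))
        table59 = table.select(keep.to_numpy(), "drop one")
        rule = DurationRule.threshold(3)
        assert eligible_animals(table59, rule, 60) == ["A0"]
        assert eligible_animals(table59, rule, 59) == ["A0", "A1"]

    def test_long_study_cohort_near_all_eligible(self):
        """A cohort sized like the subsampling source study (~144 qualifying
        visits per animal) leaves nearly every animal eligible at 60."""
        config = SyntheticCohortConfig(n_animals=25, study_days=95)
        table, _ = generate_cohort(config, seed=3)
        filtered, _ = run_qc(table)
        eligible = eligible_animals(filtered, DurationRule.threshold(3), 60)
        assert len(eligible) >= 0.9 * config.n_animals


class TestSubsampleEstimates:
    def test_full_count_equals_full_estimate(self):
        table = _uniform_table(n_animals=3, n_visits=10)
        rng = np.random.default_rng(1)
        est = subsample_estimates(table, DurationRule.threshold(3), 10, rng)
        full = arithmetic_estimates(table, "ch4", DurationRule.threshold(3))
        merged = est[est["gas"] == "ch4"].merge(full, on="animal_id")
        assert np.allclose(merged["estimate_x"], merged["estimate_y"])

    def test_precondition_breach(self):
        table = _uniform_table(n_animals=1, n_visits=5)
        with pytest.raises(ValueError, match="qualifying visits"):
            subsample_estimates(
                table, DurationRule.threshold(3), 6, np.random.default_rng(0)
            )

    def test_unbiased_for_full_mean(self):
        """Subsample means are unbiased for the full-set mean: the grand mean
        over many replicates matches within 3 Monte-Carlo SEs."""
        values = np.array([100, 110, 90, 130, 120, 80, 140, 95, 105, 150.0])
        rows = [
            clean_row("A1", start=f"2023-01-{1 + i // 2:02d}T{(i % 2) * 12:02d}:00:00",
                      duration=4.0, ch4=v)
            for i, v in enumerate(values)
        ]
        table = build_table(rows)
        rng = np.random.default_rng(7)
        reps = 2000
        draws = np.empty(reps)
        for i in range(reps):
            est = subsample_estimates(table, DurationRule.threshold(3), 5, rng)
            draws[i] = est.loc[est["gas"] == "ch4", "estimate"].iloc[0]
        se = draws.std(ddof=1) / np.sqrt(reps)
        assert abs(draws.mean() - values.mean()) < 3 * se


@pytest.fixture(scope="module")
def uniform_grid_result():
    table = _uniform_table(n_animals=6, n_visits=60)
    design = SubsamplingDesign(
        thresholds=(DurationRule.threshold(3),),
        n_grid=(5, 30, 60),
        replicates=20,
        seed=11,
    )
    return table, design, run_grid(table, design)


class TestRunGrid:
    def test_candidate_equals_gold_at_full_count(self, uniform_grid_result):
        _, _, result = uniform_grid_result
        full = result.cells[result.cells["n"] == 60]
        assert np.allclose(full["ccc"], 1.0, atol=1e-12)
        assert np.allclose(full["rmse_pct"], 0.0, atol=1e-9)

    def test_determinism(self, uniform_grid_result):
        table, design, result = uniform_grid_result
        again = run_grid(table, design)
        pd.testing.assert_frame_equal(result.cells, again.cells)

    def test_gold_standard_invariant_across_cells(self, uniform_grid_result):
        table, _, result = uniform_grid_result
        gold = result.gold
        full = arithmetic_estimates(table, "ch4", DurationRule.threshold(3))
        merged = gold[gold["gas"] == "ch4"].merge(full, on="animal_id")
        assert np.allclose(merged["estimate_x"], merged["estimate_y"])

    def test_too_few_eligible_errors(self):
        table = _uniform_table(n_animals=2, n_visits=10)
        design = SubsamplingDesign(n_grid=(5, 10), replicates=2)
        with pytest.raises(ValueError, match="eligible"):
            run_grid(table, design)


class TestMinimumVisits:
    def _fake_result(self, ccc_by_n, thr=">=3min", gas="ch4"):
        cells = pd.DataFrame(
            [
                {"gas": gas, "threshold": thr, "n": n, "replicate": 0, "ccc": c,
                 "r": 1.0, "cb": c, "rmse_pct": 0.0, "n_pairs": 10, "mean_estimate": 0.0}
                for n, c in ccc_by_n
            ]
        )
        design = SubsamplingDesign(
            n_grid=tuple(n for n, _ in ccc_by_n), replicates=1
        )
        return SubsamplingResult(design=design, cells=cells, gold=pd.DataFrame())

    def test_first_crossing(self):
        res = self._fake_result([(5, 0.50), (10, 0.85), (15, 0.92), (20, 0.95)])
        out = minimum_visits(res)
        assert out.loc[0, "n_min"] == 15 and out.loc[0, "reached"]

    def test_not_reached(self):
        res = self._fake_result([(5, 0.50), (10, 0.60)])
        out = minimum_visits(res)
        assert not out.loc[0, "reached"] and np.isnan(out.loc[0, "n_min"])

    def test_non_monotone_flagged_first_crossing(self):
        res = self._fake_result([(5, 0.91), (10, 0.88), (15, 0.93)])
        out = minimum_visits(res)
        assert out.loc[0, "n_min"] == 5
        assert not out.loc[0, "monotone"]


def test_grid_on_default_cohort_reproduces_qualitative_findings():
    """On one default synthetic cohort: replicate-mean CCC rises with n, the
    >=1-min threshold's mean estimates sit below the gold standard at every
    n, and the grid is reproducible from its seed."""
    table, _ = generate_cohort(SyntheticCohortConfig(), seed=21)
    filtered, _ = run_qc(table)
    design = SubsamplingDesign(replicates=50, seed=4)
    result = run_grid(filtered, design)
    mean_ccc = result.cells.groupby(["gas", "threshold", "n"])["ccc"].mean()
    from scipy.stats import spearmanr

    for (gas, thr), curve in mean_ccc.groupby(level=["gas", "threshold"]):
        rho = spearmanr(curve.index.get_level_values("n"), curve.to_numpy()).statistic
        assert rho > 0
    # >=1-min candidate means lie below the gold mean at every n
    gold_means = result.gold.groupby("gas")["estimate"].mean()
    cand = (
        result.cells[result.cells["threshold"] == ">=1min"]
        .groupby(["gas", "n"])["mean_estimate"]
        .mean()
    )
    for (gas, n), value in cand.items():
        gold_eligible = result.gold[
            result.gold["animal_id"].isin(result.eligible[">=1min"])
            & (result.gold["gas"] == gas)
        ]["estimate"].mean()
        assert value < gold_eligible
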