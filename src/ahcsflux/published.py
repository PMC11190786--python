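"""Published per-experiment summary statistics used for calibration and worked examples.

Four beef-cattle experiments (three grazing, one feedlot finishing; 103
steers in total) reported per-animal visit behaviour and daily gas-flux
estimates from automated head chamber systems, stratified by visit-duration
threshold and by visit-duration range.  The raw per-visit records are not
public; the printed cross-animal summaries below are used

* to calibrate the synthetic cohort generator (between-animal flux spread,
  visit rates, duration-dependent capture bias), and
* as inputs to the derived-percentage and study-length arithmetic in
  :mod:`ahcsflux.thresholds`, whose outputs are directly checkable against
  the published values.

All fluxes are g/d; durations minutes; visit rates visits per day.  Values
are cross-animal mean and SD.
"""

from __future__ import annotations

import pandas as pd

EXPERIMENTS = ("grazing_a", "grazing_b", "wheat", "feedlot")
THRESHOLD_LABELS = (">=3min", ">=2min", ">=1min", "all")

# rows: experiment, rule, item, mean, sd
_THRESHOLD_ROWS = [
    # grazing_a: 13 steers, tall-grass prairie, 6-h inter-visit lockout
    ("grazing_a", ">=3min", "duration", 4.3, 0.44),
    ("grazing_a", ">=3min", "visits_per_day", 1.5, 0.15),
    ("grazing_a", ">=3min", "n_visits", 61.1, 16.02),
    ("grazing_a", ">=3min", "co2", 7143.3, 564.93),
    ("grazing_a", ">=3min", "o2", 5230.6, 432.51),
    ("grazing_a", ">=3min", "ch4", 198.3, 22.54),
    ("grazing_a", ">=2min", "duration", 4.0, 0.37),
    ("grazing_a", ">=2min", "visits_per_day", 1.7, 0.15),
    ("grazing_a", ">=2min", "n_visits", 77.6, 20.82),
    ("grazing_a", ">=2min", "co2", 7173.8, 568.92),
    ("grazing_a", ">=2min", "o2", 5267.0, 437.75),
    ("grazing_a", ">=2min", "ch4", 194.9, 22.63),
    ("grazing_a", ">=1min", "duration", 3.6, 0.35),
    ("grazing_a", ">=1min", "visits_per_day", 2.0, 0.18),
    ("grazing_a", ">=1min", "n_visits", 93.6, 24.51),
    ("grazing_a", ">=1min", "co2", 7201.6, 548.76),
    ("grazing_a", ">=1min", "o2", 5288.3, 420.66),
    ("grazing_a", ">=1min", "ch4", 191.4, 21.04),
    ("grazing_a", "all", "duration", 2.6, 0.40),
    ("grazing_a", "all", "visits_per_day", 3.0, 0.49),
    ("grazing_a", "all", "n_visits", 150.4, 46.24),
    ("grazing_a", "all", "co2", 6891.5, 454.37),
    ("grazing_a", "all", "o2", 4958.1, 403.55),
    ("grazing_a", "all", "ch4", 151.0, 17.47),
    # grazing_b: 20 steers, tall-grass prairie, 4-h lockout
    ("grazing_b", ">=3min", "duration", 4.1, 0.39),
    ("grazing_b", ">=3min", "visits_per_day", 1.5, 0.25),
    ("grazing_b", ">=3min", "n_visits", 49.1, 17.63),
    ("grazing_b", ">=3min", "co2", 6067.5, 638.43),
    ("grazing_b", ">=3min", "o2", 4461.6, 467.95),
    ("grazing_b", ">=3min", "ch4", 176.0, 23.16),
    ("grazing_b", ">=2min", "duration", 3.8, 0.33),
    ("grazing_b", ">=2min", "visits_per_day", 1.6, 0.37),
    ("grazing_b", ">=2min", "n_visits", 64.1, 25.71),
    ("grazing_b", ">=2min", "co2", 6104.8, 643.30),
    ("grazing_b", ">=2min", "o2", 4508.6, 475.26),
    ("grazing_b", ">=2min", "ch4", 176.1, 24.67),
    ("grazing_b", ">=1min", "duration", 3.6, 0.38),
    ("grazing_b", ">=1min", "visits_per_day", 1.8, 0.47),
    ("grazing_b", ">=1min", "n_visits", 73.8, 31.48),
    ("grazing_b", ">=1min", "co2", 6091.0, 638.39),
    ("grazing_b", ">=1min", "o2", 4508.8, 471.39),
    ("grazing_b", ">=1min", "ch4", 174.7, 25.60),
    ("grazing_b", "all", "duration", 2.9, 0.39),
    ("grazing_b", "all", "visits_per_day", 2.5, 0.88),
    ("grazing_b", "all", "n_visits", 106.9, 53.19),
    ("grazing_b", "all", "co2", 5918.4, 604.65),
    ("grazing_b", "all", "o2", 4278.8, 464.70),
    ("grazing_b", "all", "ch4", 148.8, 22.56),
    # wheat: 16 head, winter-wheat pasture, 4-h lockout
    ("wheat", ">=3min", "duration", 3.7, 0.15),
    ("wheat", ">=3min", "visits_per_day", 1.6, 0.26),
    ("wheat", ">=3min", "n_visits", 51.3, 12.22),
    ("wheat", ">=3min", "co2", 6117.2, 387.38),
    ("wheat", ">=3min", "o2", 4390.3, 325.51),
    ("wheat", ">=3min", "ch4", 169.5, 13.51),
    ("wheat", ">=2min", "duration", 3.4, 0.19),
    ("wheat", ">=2min", "visits_per_day", 1.9, 0.27),
    ("wheat", ">=2min", "n_visits", 67.4, 10.16),
    ("wheat", ">=2min", "co2", 6118.5, 411.45),
    ("wheat", ">=2min", "o2", 4399.2, 336.34),
    ("wheat", ">=2min", "ch4", 168.4, 13.52),
    ("wheat", ">=1min", "duration", 3.4, 0.19),
    ("wheat", ">=1min", "visits_per_day", 2.0, 0.27),
    ("wheat", ">=1min", "n_visits", 70.5, 10.30),
    ("wheat", ">=1min", "co2", 6113.6, 404.05),
    ("wheat", ">=1min", "o2", 4398.7, 332.80),
    ("wheat", ">=1min", "ch4", 167.0, 13.68),
    ("wheat", "all", "duration", 3.0, 0.22),
    ("wheat", "all", "visits_per_day", 2.4, 0.50),
    ("wheat", "all", "n_visits", 85.8, 18.08),
    ("wheat", "all", "co2", 5983.9, 400.17),
    ("wheat", "all", "o2", 4175.6, 329.42),
    ("wheat", "all", "ch4", 150.9, 15.03),
    # feedlot: 53 finishing steers, 4-h lockout; the subsampling experiment
    # uses this cohort because nearly all animals exceed 60 qualifying visits
    ("feedlot", ">=3min", "duration", 4.4, 0.56),
    ("feedlot", ">=3min", "visits_per_day", 2.4, 0.58),
    ("feedlot", ">=3min", "n_visits", 144.0, 55.01),
    ("feedlot", ">=3min", "co2", 9860.5, 835.81),
    ("feedlot", ">=3min", "o2", 6706.4, 631.08),
    ("feedlot", ">=3min", "ch4", 149.9, 33.00),
    ("feedlot", ">=2min", "duration", 4.1, 0.52),
    ("feedlot", ">=2min", "visits_per_day", 2.7, 0.76),
    ("feedlot", ">=2min", "n_visits", 173.3, 71.22),
    ("feedlot", ">=2min", "co2", 9688.8, 804.05),
    ("feedlot", ">=2min", "o2", 6625.2, 653.94),
    ("feedlot", ">=2min", "ch4", 148.5, 34.51),
    ("feedlot", ">=1min", "duration", 3.7, 0.54),
    ("feedlot", ">=1min", "visits_per_day", 3.3, 1.12),
    ("feedlot", ">=1min", "n_visits", 218.7, 104.70),
    ("feedlot", ">=1min", "co2", 9465.2, 799.51),
    ("feedlot", ">=1min", "o2", 6439.9, 687.98),
    ("feedlot", ">=1min", "ch4", 142.6, 36.12),
    ("feedlot", "all", "duration", 2.7, 0.69),
    ("feedlot", "all", "visits_per_day", 4.9, 2.24),
    ("feedlot", "all", "n_visits", 342.0, 204.47),
    ("feedlot", "all", "co2", 8673.7, 750.93),
    ("feedlot", "all", "o2", 5423.7, 732.61),
    ("feedlot", "all", "ch4", 116.1, 37.84),
]

RANGE_LABELS = (
    ">=3min",
    "[0,1)min",
    "[1,2)min",
    "[2,3)min",
    "[3,4)min",
    "[4,5)min",
    "[5,6)min",
    ">=6min",
)

# pooled over the four experiments: per duration range, cross-animal mean/sd
# of visits per animal, visit duration and the three gas estimates, plus the
# number of animals represented in the range
_RANGE_ROWS = [
    (">=3min", 103, 101.1, 61.26, 4.2, 0.54, 8208.5, 1908.90, 5730.8, 1186.38, 164.3, 32.42),
    ("[0,1)min", 103, 81.1, 91.82, 0.37, 0.089, 6224.5, 1113.31, 3173.9, 718.90, 50.1, 21.61),
    ("[1,2)min", 101, 28.9, 32.38, 1.4, 0.12, 7261.8, 1320.61, 5012.1, 820.63, 126.6, 50.35),
    ("[2,3)min", 103, 22.9, 15.75, 2.5, 0.11, 7610.5, 1372.53, 5420.1, 955.67, 156.2, 43.08),
    ("[3,4)min", 103, 45.5, 17.78, 3.5, 0.087, 8324.0, 2014.69, 5794.6, 1240.59, 167.3, 30.84),
    ("[4,5)min", 103, 37.4, 31.79, 4.4, 0.092, 8209.2, 2009.77, 5684.8, 1214.77, 162.7, 36.00),
    ("[5,6)min", 93, 9.9, 10.21, 5.4, 0.14, 8178.4, 1856.26, 5651.4, 1186.56, 158.9, 55.56),
    (">=6min", 92, 10.4, 17.61, 7.8, 1.05, 7790.5, 1855.03, 5367.3, 11199.00, 151.6, 49.75),
]


def threshold_summary() -> pd.DataFrame:
    """Published per-experiment descriptive statistics by duration threshold.

    Tidy frame with columns ``experiment``, ``rule``, ``item``, ``mean``,
    ``sd``; ``item`` is one of ``duration``, ``visits_per_day``,
    ``n_visits``, ``co2``, ``o2``, ``ch4``.
    """
    return pd.DataFrame(
        _THRESHOLD_ROWS, columns=["experiment", "rule", "item", "mean", "sd"]
    )


def range_summary() -> pd.DataFrame:
    """Published pooled descriptive statistics by visit-duration range."""
    return pd.DataFrame(
        _RANGE_ROWS,
        columns=[
            "rule",
            "n_animals",
            "visits_mean",
            "visits_sd",
            "duration_mean",
            "duration_sd",
            "co2_mean",
            "co2_sd",
            "o2_mean",
            "o2_sd",
            "ch4_mean",
            "ch4_sd",
        ],
    )


def item_by_experiment(item: str, rule: str) -> pd.Series:
    """Published cross-animal mean of ``item`` under ``rule``, one value per
    experiment, indexed by experiment id."""
    df = threshold_summary()
    sel = df[(df["item"] == item) & (df["rule"] == rule)]
    if sel.empty:
        raise KeyError(f"no published values for item={item!r}, rule={rule!r}")
    return sel.set_index("experiment")["mean"].reindex(list(EXPERIMENTS))
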