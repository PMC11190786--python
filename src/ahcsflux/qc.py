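"""Two-stage quality control of AHCS visit records.

Stage 1 removes visits with inadequate chamber airflow (incomplete capture
of the breath cloud); stage 2 removes biologically infeasible flux values.
Boundary semantics are strict: airflow exactly at the minimum is kept, a
flux exactly at its ceiling is kept.  A record failing both stages is
charged to the airflow stage (filters run in that order).
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass

import numpy as np

from ahcsflux.io import GAS_COLUMNS, VisitTable

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class QCConfig:
    """Exclusion limits.

    Defaults: airflow < 26 L/s excluded; CO2 > 20,000 g/d, O2 > 15,000 g/d,
    CH4 > 500 g/d excluded as biologically infeasible.
    """

    airflow_min: float = 26.0
    co2_max: float = 20_000.0
    o2_max: float = 15_000.0
    ch4_max: float = 500.0

    def __post_init__(self) -> None:
        for name in ("airflow_min", "co2_max", "o2_max", "ch4_max"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be strictly positive")

    @property
    def flux_ceilings(self) -> dict[str, float]:
        return {"co2": self.co2_max, "o2": self.o2_max, "ch4": self.ch4_max}


@dataclass(frozen=True)
class QCReport:
    """Removal counts in application order (airflow first, then flux)."""

    n_input: int
    n_removed_airflow: int
    n_removed_flux: int
    n_output: int

    def __post_init__(self) -> None:
        if self.n_output != self.n_input - self.n_removed_airflow - self.n_removed_flux:
            raise ValueError("QC report counts are inconsistent")

    def to_json(self) -> str:
        return json.dumps(asdict(self))


def apply_airflow_filter(
    table: VisitTable, airflow_min: float = 26.0
) -> tuple[VisitTable, int]:
    """Keep records with airflow >= ``airflow_min`` (strict '<' excluded)."""
    air = table.df["airflow_lps"]
    if air.isna().any():
        raise ValueError("airflow missing on some records; cannot QC")
    keep = air >= airflow_min
    removed = int((~keep).sum())
    return table.select(keep, f"airflow >= {airflow_min} L/s ({removed} removed)"), removed


def apply_flux_limits(table: VisitTable, config: QCConfig) -> tuple[VisitTable, int]:
    """Remove records where ANY present gas value strictly exceeds its ceiling.

    Missing channels never trigger removal; values exactly at the ceiling
    are kept.
    """
    df = table.df
    violate = np.zeros(len(df), dtype=bool)
    for gas, ceiling in config.flux_ceilings.items():
        col = df[GAS_COLUMNS[gas]]
        violate |= (col > ceiling).fillna(False).to_numpy()
    removed = int(violate.sum())
    neg = 0
    for gas in GAS_COLUMNS.values():
        neg += int((df[gas] < 0).sum())
    if neg:
        logger.warning("retaining %d negative flux values (no lower QC bound)", neg)
    return table.select(~violate, f"flux ceilings {config.flux_ceilings} ({removed} removed)"), removed


def run_qc(table: VisitTable, config: QCConfig | None = None) -> tuple[VisitTable, QCReport]:
    """Run the airflow filter then the flux ceilings; report per-stage counts.

    Each stage's count is taken against that stage's own input, so a record
    violating both rules is counted once, by the airflow stage.
    """
    config = config or QCConfig()
    n_input = len(table)
    table1, n_air = apply_airflow_filter(table, config.airflow_min)
    table2, n_flux = apply_flux_limits(table1, config)
    report = QCReport(
        n_input=n_input,
        n_removed_airflow=n_air,
        n_removed_flux=n_flux,
        n_output=len(table2),
    )
    return table2, report
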