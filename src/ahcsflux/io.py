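"""Visit-table data model and delimited-text I/O.

The canonical in-memory container is a :class:`pandas.DataFrame` with one row
per AHCS visit (spot sample), wrapped in :class:`VisitTable` together with a
provenance trail.  Column schema (all analyses address columns by these
names; :func:`read_visit_table` accepts a mapping for vendor exports):

========== ================ =====================================
column      dtype            meaning
========== ================ =====================================
animal_id   str              animal identifier
experiment_id str            experiment/trial identifier
start_time  datetime64[ns]   visit start, naive local clock time
duration_min float            visit duration, minutes (> 0)
airflow_lps float            chamber airflow, L/s (>= 0)
co2_gpd     float            CO2 emission, g/d (NaN = missing)
o2_gpd      float            O2 consumption, g/d (NaN = missing)
ch4_gpd     float            CH4 emission, g/d (NaN = missing)
========== ================ =====================================
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

COLUMNS = [
    "animal_id",
    "experiment_id",
    "start_time",
    "duration_min",
    "airflow_lps",
    "co2_gpd",
    "o2_gpd",
    "ch4_gpd",
]

#: analysis gas name -> visit-table column
GAS_COLUMNS = {"co2": "co2_gpd", "o2": "o2_gpd", "ch4": "ch4_gpd"}
GASES = tuple(GAS_COLUMNS)


@dataclass
class VisitTable:
    """Ordered collection of visit records plus a provenance trail.

    ``diagnostics`` holds per-row messages for records rejected on read
    (unparseable timestamp, nonpositive duration); they are never silently
    dropped.
    """

    df: pd.DataFrame
    provenance: list[str] = field(default_factory=list)
    diagnostics: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        missing = [c for c in COLUMNS if c not in self.df.columns]
        if missing:
            raise ValueError(f"visit table missing columns: {missing}")
        # an animal belongs to exactly one experiment
        n_exp = self.df.groupby("animal_id", observed=True)["experiment_id"].nunique()
        bad = n_exp[n_exp > 1]
        if len(bad):
            raise ValueError(
                f"animals assigned to multiple experiments: {list(bad.index)}"
            )

    def __len__(self) -> int:
        return len(self.df)

    def select(self, mask: np.ndarray | pd.Series, note: str) -> "VisitTable":
        """Return a new table keeping rows where ``mask`` is True."""
        return VisitTable(
            self.df.loc[np.asarray(mask)].reset_index(drop=True),
            provenance=[*self.provenance, note],
            diagnostics=list(self.diagnostics),
        )

    def with_note(self, note: str) -> "VisitTable":
        return VisitTable(self.df, [*self.provenance, note], list(self.diagnostics))


def _coerce(df: pd.DataFrame, source: str) -> VisitTable:
    """Validate dtypes/invariants row-wise; reject bad rows with diagnostics."""
    df = df.copy()
    df["start_time"] = pd.to_datetime(df["start_time"], errors="coerce", format="mixed")
    for col in ["duration_min", "airflow_lps", "co2_gpd", "o2_gpd", "ch4_gpd"]:
        df[col] = pd.to_numeric(df[col], errors="coerce").astype(float)
    df["animal_id"] = df["animal_id"].astype(str)
    df["experiment_id"] = df["experiment_id"].astype(str)

    diagnostics: list[str] = []
    bad_time = df["start_time"].isna()
    bad_dur = ~(df["duration_min"] > 0)  # catches NaN and <= 0
    bad_air = df["airflow_lps"].isna() | (df["airflow_lps"] < 0)
    for idx in df.index[bad_time]:
        diagnostics.append(f"row {idx}: unparseable start_time")
    for idx in df.index[bad_dur & ~bad_time]:
        diagnostics.append(f"row {idx}: nonpositive or missing duration")
    for idx in df.index[bad_air & ~bad_time & ~bad_dur]:
        diagnostics.append(f"row {idx}: negative or missing airflow")
    keep = ~(bad_time | bad_dur | bad_air)
    out = df.loc[keep, COLUMNS].reset_index(drop=True)
    if len(out) == 0:
        raise ValueError(f"{source}: zero valid visit records")
    table = VisitTable(out, provenance=[source])
    table.diagnostics = diagnostics
    return table


def read_visit_table(
    path: str | Path, schema: dict[str, str] | None = None
) -> VisitTable:
    """Read a delimited visit table (CSV with header).

    Parameters
    ----------
    path
        CSV file, one row per visit.
    schema
        Optional mapping ``{canonical_name: column_name_in_file}`` for vendor
        exports whose headers differ from the default schema.

    Raises
    ------
    FileNotFoundError
        If ``path`` does not exist.
    ValueError
        If a mapped column is absent or no valid rows remain.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    raw = pd.read_csv(path)
    if schema:
        missing = [src for src in schema.values() if src not in raw.columns]
        if missing:
            raise ValueError(f"{path}: mapped columns not in file: {missing}")
        raw = raw.rename(columns={v: k for k, v in schema.items()})
    missing = [c for c in COLUMNS if c not in raw.columns]
    if missing:
        raise ValueError(f"{path}: missing columns: {missing}")
    return _coerce(raw, source=str(path))


def write_visit_table(table: VisitTable, path: str | Path) -> None:
    """Write a visit table as CSV (header row, ISO 8601 timestamps, empty
    fields for missing gas values)."""
    if len(table) == 0:
        raise ValueError("refusing to write an empty visit table")
    out = table.df.copy()
    out["start_time"] = out["start_time"].dt.strftime("%Y-%m-%dT%H:%M:%S")
    out.to_csv(path, index=False, float_format="%.10g")


def from_records(df: pd.DataFrame, note: str = "in-memory") -> VisitTable:
    """Build a validated :class:`VisitTable` from an in-memory frame."""
    return _coerce(df, source=note)


def per_animal_summary(table: VisitTable) -> pd.DataFrame:
    """Per-animal visit behaviour summary.

    ``observation_days`` is the inclusive calendar-day span of the animal's
    visits (last date - first date + 1), so a single-day animal has span 1,
    and ``visits_per_day = n_visits / observation_days``.

    Returns a frame indexed by ``animal_id`` with columns ``n_visits``,
    ``observation_days``, ``visits_per_day``, ``duration_mean``,
    ``duration_sd`` (NaN when a single visit).
    """
    if len(table) == 0:
        raise ValueError("empty visit table")
    df = table.df
    g = df.groupby("animal_id", observed=True)
    dates = df["start_time"].dt.normalize()
    span = (
        dates.groupby(df["animal_id"], observed=True).max()
        - dates.groupby(df["animal_id"], observed=True).min()
    ).dt.days + 1
    out = pd.DataFrame(
        {
            "n_visits": g.size(),
            "observation_days": span.astype(float),
            "duration_mean": g["duration_min"].mean(),
            "duration_sd": g["duration_min"].std(ddof=1),
        }
    )
    out["visits_per_day"] = out["n_visits"] / out["observation_days"]
    return out[
        ["n_visits", "observation_days", "visits_per_day", "duration_mean", "duration_sd"]
    ]
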