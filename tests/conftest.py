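import numpy as np
import pandas as pd
import pytest

from ahcsflux.io import COLUMNS, VisitTable, from_records


def build_table(records, experiment="E1"):
    """Build a VisitTable from (animal, start, duration, airflow, co2, o2, ch4) tuples."""
    df = pd.DataFrame(
        records,
        columns=[
            "animal_id",
            "start_time",
            "duration_min",
            "airflow_lps",
            "co2_gpd",
            "o2_gpd",
            "ch4_gpd",
        ],
    )
    df.insert(1, "experiment_id", experiment)
    return from_records(df[COLUMNS])


def clean_row(animal="A1", start="2023-01-01T08:00:00", duration=3.5, airflow=30.0,
              co2=8000.0, o2=5500.0, ch4=150.0):
    return (animal, start, duration, airflow, co2, o2, ch4)


@pytest.fixture
def three_visit_animal():
    """One animal with visits (duration, ch4) = (3.5, 160), (2.5, 150), (0.5, 60)."""
    return build_table(
        [
            clean_row(duration=3.5, ch4=160.0, start="2023-01-01T07:00:00"),
            clean_row(duration=2.5, ch4=150.0, start="2023-01-01T13:00:00"),
            clean_row(duration=0.5, ch4=60.0, start="2023-01-01T20:00:00"),
        ]
    )


@pytest.fixture
def qc_fixture_table():
    """Ten records with planted violations, hand-enumerable.

    Three fail the airflow screen (one of those also has CH4 > 500); one
    further record fails the CH4 ceiling.  Two records sit exactly on the
    boundaries (airflow 26.0, CH4 500.0) and must be kept.
    """
    rows = [
        clean_row("A1", airflow=25.0),                      # airflow removed
        clean_row("A1", airflow=20.0, ch4=600.0),           # airflow removed (double)
        clean_row("A2", airflow=25.9),                      # airflow removed
        clean_row("A2", airflow=26.0, ch4=500.0),           # boundary: kept
        clean_row("A3", airflow=30.0, ch4=500.1),           # flux removed
        clean_row("A3"),
        clean_row("A4"),
        clean_row("A4"),
        clean_row("A5"),
        clean_row("A5"),
    ]
    return build_table(rows)
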