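"""Cohort CSV reading and writing.

The cohort CSV schema is one row per participant with columns::

    id, sex, age, height, weight, wc, tg, hdl, fpg, sbp, dbp,
    antihypertensive_med, antidiabetic_med, diabetes_history,
    education, marital_status, residence, smoking, drinking,
    activities, exercise, chronic_disease_band

Lengths are m (height) / cm (wc), weight kg, pressures mmHg.  Because
published index formulas mix mg/dL and mmol/L, the analyte columns
(tg, hdl, fpg) carry **no implicit unit**: the caller must declare the unit
of each, and values are converted to the canonical mmol/L on ingest.
Rows violating the participant invariants are collected into a rejects
report rather than aborting the run.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from metscreen.cohort import COVARIATE_NAMES
from metscreen.indices import ParticipantRecord
from metscreen.units import Unit, convert_analyte

REQUIRED_COLUMNS = (
    "id",
    "sex",
    "age",
    "height",
    "weight",
    "wc",
    "tg",
    "hdl",
    "fpg",
    "sbp",
    "dbp",
    "antihypertensive_med",
    "antidiabetic_med",
    "diabetes_history",
)

ANALYTE_COLUMNS = {"tg": "TG", "hdl": "HDL", "fpg": "glucose"}

_FLAG_COLUMNS = ("antihypertensive_med", "antidiabetic_med", "diabetes_history")


def read_cohort_csv(
    path, unit_declarations: dict[str, Unit | str]
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Read and validate a cohort CSV.

    Parameters
    ----------
    path
        CSV file with the documented schema.
    unit_declarations
        Unit tag for each analyte column, e.g.
        ``{"tg": "mg_dL", "hdl": "mg_dL", "fpg": "mg_dL"}``.  All three of
        ``tg, hdl, fpg`` must be declared.

    Returns
    -------
    (cohort, rejects)
        ``cohort`` holds the accepted rows with analytes converted to
        mmol/L; ``rejects`` has columns ``id, reason``.  Row order is
        preserved; every input row lands in exactly one of the two.
    """
    missing_units = set(ANALYTE_COLUMNS) - set(unit_declarations)
    if missing_units:
        raise ValueError(f"unit declarations missing for {sorted(missing_units)}")
    units = {col: Unit(unit_declarations[col]) for col in ANALYTE_COLUMNS}

    frame = pd.read_csv(path)
    missing_cols = set(REQUIRED_COLUMNS) - set(frame.columns)
    if missing_cols:
        raise ValueError(f"required columns missing: {sorted(missing_cols)}")

    for col, analyte in ANALYTE_COLUMNS.items():
        frame[col] = [
            convert_analyte(v, analyte, units[col], Unit.MMOL_L)
            if np.isfinite(v) and v >= 0
            else np.nan
            for v in frame[col].astype(float)
        ]
    for col in _FLAG_COLUMNS:
        frame[col] = frame[col].astype(bool)

    accepted_idx, reject_rows = [], []
    for idx, row in frame.iterrows():
        record = ParticipantRecord(
            id=str(row["id"]),
            sex=row["sex"],
            age=float(row["age"]),
            height=float(row["height"]),
            weight=float(row["weight"]),
            wc=float(row["wc"]),
            tg=float(row["tg"]) if np.isfinite(row["tg"]) else -1.0,
            hdl=float(row["hdl"]) if np.isfinite(row["hdl"]) else -1.0,
            fpg=float(row["fpg"]) if np.isfinite(row["fpg"]) else -1.0,
            sbp=float(row["sbp"]),
            dbp=float(row["dbp"]),
        )
        try:
            record.validate()
            accepted_idx.append(idx)
        except ValueError as err:
            reject_rows.append({"id": str(row["id"]), "reason": str(err)})

    cohort = frame.loc[accepted_idx].reset_index(drop=True)
    for cov in COVARIATE_NAMES:
        if cov in cohort.columns:
            cohort[cov] = cohort[cov].astype("category")
    return cohort, pd.DataFrame(reject_rows, columns=["id", "reason"])


def write_cohort_csv(cohort: pd.DataFrame, path) -> None:
    """Write a cohort on the canonical scales (analytes in mmol/L)."""
    cohort.to_csv(path, index=False)
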