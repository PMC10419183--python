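"""Analyte unit conversions.

Index formulas disagree on the scale of lipid and glucose inputs: the lipid
accumulation product wants triglycerides in mmol/L while the TyG index wants
both triglycerides and glucose in mg/dL, and the diagnostic thresholds for
metabolic syndrome are printed in mg/dL.  All records are stored internally
in mmol/L (the scale Chinese assay reports use) and each formula converts
explicitly to whatever its definition names.

Conversion factors are the standard clinical molar-mass factors, in mg/dL
per mmol/L.
"""

from __future__ import annotations

from enum import Enum


class Unit(str, Enum):
    """Enumerated measurement unit tags."""

    CM = "cm"
    M = "m"
    KG = "kg"
    MMHG = "mmHg"
    MG_DL = "mg_dL"
    MMOL_L = "mmol_L"
    YEARS = "years"


#: mg/dL per mmol/L, by analyte.
MG_DL_PER_MMOL_L: dict[str, float] = {
    "TG": 88.57,       # triglycerides (average molar mass ~885.7 g/mol)
    "glucose": 18.016,  # glucose (180.16 g/mol)
    "HDL": 38.67,      # HDL cholesterol (386.65 g/mol)
}

_CONCENTRATION_UNITS = {Unit.MG_DL, Unit.MMOL_L}


def convert_analyte(
    value: float,
    analyte: str,
    from_unit: Unit | str,
    to_unit: Unit | str,
) -> float:
    """Rescale an analyte concentration between mg/dL and mmol/L.

    Parameters
    ----------
    value
        Non-negative concentration on the ``from_unit`` scale.
    analyte
        One of ``"TG"``, ``"glucose"``, ``"HDL"``.
    from_unit, to_unit
        ``Unit.MG_DL`` or ``Unit.MMOL_L`` (or their string tags).

    Returns
    -------
    float
        ``value`` on the ``to_unit`` scale; identity when the units match.

    Raises
    ------
    ValueError
        Unknown analyte, non-concentration unit, or negative value.
    """
    if analyte not in MG_DL_PER_MMOL_L:
        raise ValueError(
            f"unknown analyte {analyte!r}; expected one of "
            f"{sorted(MG_DL_PER_MMOL_L)}"
        )
    from_unit = Unit(from_unit)
    to_unit = Unit(to_unit)
    if from_unit not in _CONCENTRATION_UNITS or to_unit not in _CONCENTRATION_UNITS:
        raise ValueError(
            f"analyte conversion requires mg_dL or mmol_L, got "
            f"{from_unit.value!r} -> {to_unit.value!r}"
        )
    if value < 0:
        raise ValueError(f"analyte concentration must be >= 0, got {value}")
    if from_unit == to_unit:
        return value
    factor = MG_DL_PER_MMOL_L[analyte]
    if from_unit == Unit.MMOL_L:  # -> mg/dL
        return value * factor
    return value / factor
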