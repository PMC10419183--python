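"""The 13 obesity- and lipid-related indices.

Every calculator accepts scalars or numpy arrays and broadcasts; sex-specific
formulas (VAI, LAP, CVAI) take ``sex`` as ``"male"``/``"female"`` scalars or
arrays.  Interface conventions:

* waist circumference (WC) is given in **cm**; conversions to metres inside
  ABSI, BRI and the conicity index are internal;
* height is given in **m**;
* TG, HDL-C and fasting glucose are given in **mmol/L**; the TyG index
  converts both analytes to mg/dL internally, as its definition requires;
* ABSI is returned on a ×100 scale (named constant ``ABSI_SCALE``) so that
  physiologic values land near 8 rather than 0.08, matching how the index is
  conventionally tabulated in Chinese cohort studies;
* the conicity index uses the standard normalising constant 0.109
  (``CONICITY_CONSTANT``).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np
import pandas as pd

from metscreen.units import convert_analyte, Unit

#: canonical column order of the index panel
INDEX_NAMES: tuple[str, ...] = (
    "wc",
    "bmi",
    "whtr",
    "vai",
    "absi",
    "bri",
    "lap",
    "ci",
    "cvai",
    "tyg",
    "tyg_bmi",
    "tyg_wc",
    "tyg_whtr",
)

#: reporting scale for ABSI (dimensionless ratio ×100)
ABSI_SCALE = 100.0

#: conicity-index normalising constant (m·kg^-1/2·m^1/2)
CONICITY_CONSTANT = 0.109

_SEXES = ("male", "female")


class DomainError(ValueError):
    """An index formula received an argument outside its domain."""


def _require_positive(**kwargs: Any) -> None:
    for name, value in kwargs.items():
        if np.any(np.asarray(value) <= 0):
            raise DomainError(f"{name} must be > 0")


def _sex_mask(sex: Any) -> np.ndarray:
    sex_arr = np.asarray(sex)
    valid = np.isin(sex_arr, _SEXES)
    if not np.all(valid):
        bad = np.unique(sex_arr[~valid]) if sex_arr.ndim else sex_arr
        raise DomainError(f"sex must be 'male' or 'female', got {bad}")
    return sex_arr == "male"


def compute_bmi(weight, height):
    """Body mass index: weight (kg) / height (m) squared."""
    _require_positive(weight=weight, height=height)
    return np.asarray(weight, float) / np.asarray(height, float) ** 2


def compute_whtr(wc, height):
    """Waist-to-height ratio with both lengths on the cm scale."""
    _require_positive(wc=wc, height=height)
    return np.asarray(wc, float) / (np.asarray(height, float) * 100.0)


def compute_vai(sex, wc, bmi, tg, hdl):
    """Visceral adiposity index, sex-specific.

    Male:   (WC / (39.68 + 1.88·BMI)) · (TG/1.03) · (1.31/HDL)
    Female: (WC / (36.58 + 1.89·BMI)) · (TG/0.81) · (1.52/HDL)

    with WC in cm and TG/HDL in mmol/L.
    """
    _require_positive(wc=wc, bmi=bmi, tg=tg, hdl=hdl)
    male = _sex_mask(sex)
    wc = np.asarray(wc, float)
    bmi = np.asarray(bmi, float)
    tg = np.asarray(tg, float)
    hdl = np.asarray(hdl, float)
    male_vai = wc / (39.68 + 1.88 * bmi) * (tg / 1.03) * (1.31 / hdl)
    female_vai = wc / (36.58 + 1.89 * bmi) * (tg / 0.81) * (1.52 / hdl)
    return np.where(male, male_vai, female_vai)


def compute_absi(wc, bmi, height):
    """A body shape index: WC_m / (BMI^(2/3) · height^(1/2)), ×100."""
    _require_positive(wc=wc, bmi=bmi, height=height)
    wc_m = np.asarray(wc, float) / 100.0
    return ABSI_SCALE * wc_m / (
        np.asarray(bmi, float) ** (2.0 / 3.0) * np.asarray(height, float) ** 0.5
    )


def compute_bri(wc, height):
    """Body roundness index.

    364.2 − 365.5·sqrt(1 − (WC_m/2π)² / (0.5·height)²).  Requires the waist
    radius to be at most half the height (radicand in [0, 1]); outside that
    the body-ellipse model is undefined and a :class:`DomainError` is raised.
    """
    _require_positive(wc=wc, height=height)
    wc_m = np.asarray(wc, float) / 100.0
    radicand = 1.0 - (wc_m / (2.0 * np.pi)) ** 2 / (0.5 * np.asarray(height, float)) ** 2
    if np.any(radicand < 0):
        raise DomainError("waist circumference too large relative to height for BRI")
    return 364.2 - 365.5 * np.sqrt(radicand)


def compute_lap(sex, wc, tg):
    """Lipid accumulation product: (WC − 65)·TG male, (WC − 58)·TG female.

    WC in cm, TG in mmol/L.  Negative values (waist below the sex offset)
    are legitimate scores and are not clamped.
    """
    _require_positive(tg=tg)
    male = _sex_mask(sex)
    wc = np.asarray(wc, float)
    tg = np.asarray(tg, float)
    return np.where(male, (wc - 65.0) * tg, (wc - 58.0) * tg)


def compute_conicity(wc, weight, height):
    """Conicity index: WC_m / (0.109 · sqrt(weight_kg / height_m))."""
    _require_positive(wc=wc, weight=weight, height=height)
    wc_m = np.asarray(wc, float) / 100.0
    return wc_m / (
        CONICITY_CONSTANT * np.sqrt(np.asarray(weight, float) / np.asarray(height, float))
    )


def compute_cvai(sex, age, bmi, wc, tg, hdl):
    """Chinese visceral adiposity index, sex-specific linear score.

    Male:   −267.93 + 0.68·age + 0.03·BMI + 4.00·WC + 22.00·log10(TG) − 16.32·HDL
    Female: −187.32 + 1.71·age + 4.32·BMI + 1.12·WC + 39.76·log10(TG) − 11.66·HDL

    with age in years, WC in cm, TG and HDL in mmol/L.
    """
    _require_positive(tg=tg)
    male = _sex_mask(sex)
    age = np.asarray(age, float)
    bmi = np.asarray(bmi, float)
    wc = np.asarray(wc, float)
    log_tg = np.log10(np.asarray(tg, float))
    hdl = np.asarray(hdl, float)
    male_cvai = -267.93 + 0.68 * age + 0.03 * bmi + 4.00 * wc + 22.00 * log_tg - 16.32 * hdl
    female_cvai = -187.32 + 1.71 * age + 4.32 * bmi + 1.12 * wc + 39.76 * log_tg - 11.66 * hdl
    return np.where(male, male_cvai, female_cvai)


def compute_tyg(tg, fpg):
    """Triglyceride-glucose index: ln(TG[mg/dL] · glucose[mg/dL] / 2).

    Inputs arrive in mmol/L and are converted internally.
    """
    _require_positive(tg=tg, fpg=fpg)
    tg_mgdl = np.asarray(tg, float) * 88.57
    fpg_mgdl = np.asarray(fpg, float) * 18.016
    return np.log(tg_mgdl * fpg_mgdl / 2.0)


def compute_tyg_combos(tyg, bmi, wc, whtr):
    """TyG anthropometric products: (TyG·BMI, TyG·WC, TyG·WHtR)."""
    tyg = np.asarray(tyg, float)
    return (
        tyg * np.asarray(bmi, float),
        tyg * np.asarray(wc, float),
        tyg * np.asarray(whtr, float),
    )


# --------------------------------------------------------------------------
# participant records and panel composition


@dataclass
class ParticipantRecord:
    """One person's raw measurements, medications, and covariates.

    Lengths in m (height) and cm (WC); weight in kg; analytes in mmol/L;
    pressures in mmHg; age in years.
    """

    id: str
    sex: str
    age: float
    height: float
    weight: float
    wc: float
    tg: float
    hdl: float
    fpg: float
    sbp: float
    dbp: float
    antihypertensive_med: bool = False
    antidiabetic_med: bool = False
    diabetes_history: bool = False
    covariates: dict[str, str] = field(default_factory=dict)

    def validate(self, age_floor: float = 45.0) -> None:
        """Raise :class:`DomainError` if any invariant is violated."""
        if self.sex not in _SEXES:
            raise DomainError(f"record {self.id}: sex must be 'male' or 'female'")
        checks = [
            (0.5 < self.height < 2.5, f"height {self.height} m out of range (0.5, 2.5)"),
            (30.0 < self.wc < 200.0, f"wc {self.wc} cm out of range (30, 200)"),
            (20.0 < self.weight < 200.0, f"weight {self.weight} kg out of range (20, 200)"),
            (self.tg > 0, f"tg {self.tg} must be > 0"),
            (self.hdl > 0, f"hdl {self.hdl} must be > 0"),
            (self.fpg > 0, f"fpg {self.fpg} must be > 0"),
            (self.age >= age_floor, f"age {self.age} below study floor {age_floor}"),
        ]
        for ok, msg in checks:
            if not ok:
                raise DomainError(f"record {self.id}: {msg}")


@dataclass
class IndexPanel:
    """The 13 computed index values for one participant."""

    wc: float
    bmi: float
    whtr: float
    vai: float
    absi: float
    bri: float
    lap: float
    ci: float
    cvai: float
    tyg: float
    tyg_bmi: float
    tyg_wc: float
    tyg_whtr: float

    def as_dict(self) -> dict[str, float]:
        return {name: getattr(self, name) for name in INDEX_NAMES}


def compute_index_panel(record: ParticipantRecord) -> IndexPanel:
    """Compute all 13 indices for one participant.

    Domain errors from individual formulas are re-raised with the record id
    attached so a cohort run can report them per record and continue.
    """
    record.validate()
    try:
        bmi = float(compute_bmi(record.weight, record.height))
        whtr = float(compute_whtr(record.wc, record.height))
        tyg = float(compute_tyg(record.tg, record.fpg))
        tyg_bmi, tyg_wc, tyg_whtr = compute_tyg_combos(tyg, bmi, record.wc, whtr)
        return IndexPanel(
            wc=record.wc,
            bmi=bmi,
            whtr=whtr,
            vai=float(compute_vai(record.sex, record.wc, bmi, record.tg, record.hdl)),
            absi=float(compute_absi(record.wc, bmi, record.height)),
            bri=float(compute_bri(record.wc, record.height)),
            lap=float(compute_lap(record.sex, record.wc, record.tg)),
            ci=float(compute_conicity(record.wc, record.weight, record.height)),
            cvai=float(
                compute_cvai(record.sex, record.age, bmi, record.wc, record.tg, record.hdl)
            ),
            tyg=tyg,
            tyg_bmi=float(tyg_bmi),
            tyg_wc=float(tyg_wc),
            tyg_whtr=float(tyg_whtr),
        )
    except DomainError as err:
        raise DomainError(f"record {record.id}: {err}") from err


def panel_frame(cohort: pd.DataFrame) -> pd.DataFrame:
    """Vectorised index panel for a cohort DataFrame.

    Expects columns ``sex, age, height, weight, wc, tg, hdl, fpg`` on the
    canonical scales; returns a DataFrame with one column per index, aligned
    to the cohort's row index.
    """
    bmi = compute_bmi(cohort["weight"].to_numpy(), cohort["height"].to_numpy())
    whtr = compute_whtr(cohort["wc"].to_numpy(), cohort["height"].to_numpy())
    tyg = compute_tyg(cohort["tg"].to_numpy(), cohort["fpg"].to_numpy())
    sex = cohort["sex"].to_numpy()
    wc = cohort["wc"].to_numpy(float)
    tg = cohort["tg"].to_numpy(float)
    hdl = cohort["hdl"].to_numpy(float)
    tyg_bmi, tyg_wc, tyg_whtr = compute_tyg_combos(tyg, bmi, wc, whtr)
    return pd.DataFrame(
        {
            "wc": wc,
            "bmi": bmi,
            "whtr": whtr,
            "vai": compute_vai(sex, wc, bmi, tg, hdl),
            "absi": compute_absi(wc, bmi, cohort["height"].to_numpy(float)),
            "bri": compute_bri(wc, cohort["height"].to_numpy(float)),
            "lap": compute_lap(sex, wc, tg),
            "ci": compute_conicity(
                wc, cohort["weight"].to_numpy(float), cohort["height"].to_numpy(float)
            ),
            "cvai": compute_cvai(
                sex, cohort["age"].to_numpy(float), bmi, wc, tg, hdl
            ),
            "tyg": tyg,
            "tyg_bmi": tyg_bmi,
            "tyg_wc": tyg_wc,
            "tyg_whtr": tyg_whtr,
        },
        index=cohort.index,
    )
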