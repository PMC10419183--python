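"""NCEP ATP III metabolic-syndrome components and diagnosis.

The five components, with Chinese waist thresholds:

* central obesity — WC ≥ 90 cm (men) / ≥ 80 cm (women);
* elevated triglycerides — TG ≥ 150 mg/dL;
* low HDL-C — HDL < 40 mg/dL (men) / < 50 mg/dL (women), strict;
* elevated blood pressure — SBP ≥ 130 or DBP ≥ 85 mmHg, or
  antihypertensive therapy;
* elevated fasting glucose — FPG ≥ 100 mg/dL, or antidiabetic medication,
  or self-reported diabetes history.

Metabolic syndrome is diagnosed when at least 3 of the 5 are present.
Therapy overrides attach only to blood pressure and glucose; lipid-lowering
treatment is not part of the definition used here.

Analytes are stored in mmol/L and compared in mg/dL.  Comparisons carry a
one-part-in-10^9 relative guard so the diagnosis is invariant to whether a
value was originally supplied in mg/dL or mmol/L (the round trip through the
molar conversion factor is otherwise not bit-exact at the thresholds).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from metscreen.indices import ParticipantRecord
from metscreen.units import MG_DL_PER_MMOL_L

WC_THRESHOLD_CM = {"male": 90.0, "female": 80.0}
TG_THRESHOLD_MGDL = 150.0
HDL_THRESHOLD_MGDL = {"male": 40.0, "female": 50.0}
SBP_THRESHOLD = 130.0
DBP_THRESHOLD = 85.0
FPG_THRESHOLD_MGDL = 100.0

#: age bands used for stratified prevalence, [lo, hi] inclusive
AGE_BANDS = ((45, 54), (55, 64), (65, 74), (75, None))

_REL_GUARD = 1e-9

COMPONENT_NAMES = (
    "central_obesity",
    "elevated_tg",
    "low_hdl",
    "elevated_bp",
    "elevated_fpg",
)


@dataclass
class MetSComponents:
    """The five component flags plus the 3-of-5 diagnosis."""

    central_obesity: bool
    elevated_tg: bool
    low_hdl: bool
    elevated_bp: bool
    elevated_fpg: bool

    @property
    def n_components(self) -> int:
        return sum(
            (
                self.central_obesity,
                self.elevated_tg,
                self.low_hdl,
                self.elevated_bp,
                self.elevated_fpg,
            )
        )

    @property
    def mets(self) -> bool:
        return self.n_components >= 3


def _ge(value, threshold):
    """value >= threshold with a relative guard against conversion jitter."""
    return np.asarray(value) >= threshold * (1.0 - _REL_GUARD)


def _lt(value, threshold):
    """value < threshold, strict, with the same guard."""
    return np.asarray(value) < threshold * (1.0 - _REL_GUARD)


def component_flags(record: ParticipantRecord) -> MetSComponents:
    """Evaluate the five component criteria for one participant."""
    record.validate()
    flags = components_frame(
        pd.DataFrame(
            {
                "sex": [record.sex],
                "wc": [record.wc],
                "tg": [record.tg],
                "hdl": [record.hdl],
                "fpg": [record.fpg],
                "sbp": [record.sbp],
                "dbp": [record.dbp],
                "antihypertensive_med": [record.antihypertensive_med],
                "antidiabetic_med": [record.antidiabetic_med],
                "diabetes_history": [record.diabetes_history],
            }
        )
    ).iloc[0]
    return MetSComponents(*(bool(flags[name]) for name in COMPONENT_NAMES))


def components_frame(cohort: pd.DataFrame) -> pd.DataFrame:
    """Vectorised component flags for a cohort.

    Returns a boolean DataFrame with the five component columns plus
    ``n_components`` and ``mets``, aligned to the cohort's row index.
    """
    male = cohort["sex"].to_numpy() == "male"
    wc_thr = np.where(male, WC_THRESHOLD_CM["male"], WC_THRESHOLD_CM["female"])
    hdl_thr = np.where(male, HDL_THRESHOLD_MGDL["male"], HDL_THRESHOLD_MGDL["female"])

    tg_mgdl = cohort["tg"].to_numpy(float) * MG_DL_PER_MMOL_L["TG"]
    hdl_mgdl = cohort["hdl"].to_numpy(float) * MG_DL_PER_MMOL_L["HDL"]
    fpg_mgdl = cohort["fpg"].to_numpy(float) * MG_DL_PER_MMOL_L["glucose"]

    central_obesity = _ge(cohort["wc"].to_numpy(float), wc_thr)
    elevated_tg = _ge(tg_mgdl, TG_THRESHOLD_MGDL)
    low_hdl = _lt(hdl_mgdl, hdl_thr)
    elevated_bp = (
        _ge(cohort["sbp"].to_numpy(float), SBP_THRESHOLD)
        | _ge(cohort["dbp"].to_numpy(float), DBP_THRESHOLD)
        | cohort["antihypertensive_med"].to_numpy(bool)
    )
    elevated_fpg = (
        _ge(fpg_mgdl, FPG_THRESHOLD_MGDL)
        | cohort["antidiabetic_med"].to_numpy(bool)
        | cohort["diabetes_history"].to_numpy(bool)
    )

    out = pd.DataFrame(
        {
            "central_obesity": central_obesity,
            "elevated_tg": elevated_tg,
            "low_hdl": low_hdl,
            "elevated_bp": elevated_bp,
            "elevated_fpg": elevated_fpg,
        },
        index=cohort.index,
    )
    out["n_components"] = out[list(COMPONENT_NAMES)].sum(axis=1)
    out["mets"] = out["n_components"] >= 3
    return out


def age_band_label(age: float) -> str:
    """Map an age in years to its reporting band ('45-54' ... '>=75').

    Bands are half-open on the continuous scale: '45-54' covers [45, 55),
    so a 54.6-year-old reports in the 45-54 band.
    """
    for lo, hi in AGE_BANDS:
        if hi is None:
            if age >= lo:
                return f">={lo}"
        elif lo <= age < hi + 1:
            return f"{lo}-{hi}"
    raise ValueError(f"age {age} below the study floor")


def diagnose_cohort(cohort: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-record diagnosis plus stratified prevalence.

    Returns ``(flags, prevalence)`` where ``flags`` is the output of
    :func:`components_frame` and ``prevalence`` has one row per stratum
    (overall, each sex, each sex × age band) with columns
    ``stratum, n, n_mets, prevalence_percent`` (percent rounded to 2
    decimals).
    """
    if len(cohort) == 0:
        raise ValueError("empty cohort")
    flags = components_frame(cohort)
    mets = flags["mets"]

    rows = []

    def add(stratum: str, mask: pd.Series) -> None:
        n = int(mask.sum())
        n_mets = int((mets & mask).sum())
        pct = round(100.0 * n_mets / n, 2) if n else float("nan")
        rows.append({"stratum": stratum, "n": n, "n_mets": n_mets, "prevalence_percent": pct})

    everyone = pd.Series(True, index=cohort.index)
    add("overall", everyone)
    bands = cohort["age"].map(age_band_label)
    for sex in ("male", "female"):
        sex_mask = cohort["sex"] == sex
        add(sex, sex_mask)
        for lo, hi in AGE_BANDS:
            label = f">={lo}" if hi is None else f"{lo}-{hi}"
            add(f"{sex} {label}", sex_mask & (bands == label))
    return flags, pd.DataFrame(rows)
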