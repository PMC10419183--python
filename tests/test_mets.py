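import dataclasses

import numpy as np
import pandas as pd
import pytest

from metscreen.indices import ParticipantRecord
from metscreen.mets import (
    COMPONENT_NAMES,
    age_band_label,
    component_flags,
    components_frame,
    diagnose_cohort,
)
from metscreen.units import MG_DL_PER_MMOL_L


def make_record(sex="male", wc=85.0, tg_mgdl=100.0, hdl_mgdl=60.0, sbp=120.0,
                dbp=80.0, fpg_mgdl=90.0, **flags):
    """Record with analytes specified in mg/dL (converted to storage units)."""
    return ParticipantRecord(
        id="t",
        sex=sex,
        age=60.0,
        height=1.65,
        weight=65.0,
        wc=wc,
        tg=tg_mgdl / MG_DL_PER_MMOL_L["TG"],
        hdl=hdl_mgdl / MG_DL_PER_MMOL_L["HDL"],
        fpg=fpg_mgdl / MG_DL_PER_MMOL_L["glucose"],
        sbp=sbp,
        dbp=dbp,
        **flags,
    )


class TestBoundarySemantics:
    """Threshold semantics exactly as the diagnostic definition prints them:
    >= for cut-ins, strict < for HDL."""

    def test_male_exact_thresholds(self):
        # WC 90 in, TG 150 in, HDL 40 out (strict <), BP 129/84 out, FPG 99 out
        c = component_flags(
            make_record(sex="male", wc=90.0, tg_mgdl=150.0, hdl_mgdl=40.0,
                        sbp=129.0, dbp=84.0, fpg_mgdl=99.0)
        )
        assert (c.central_obesity, c.elevated_tg, c.low_hdl, c.elevated_bp,
                c.elevated_fpg) == (True, True, False, False, False)
        assert c.n_components == 2 and not c.mets

    def test_female_waist_boundary(self):
        c = component_flags(make_record(sex="female", wc=80.0, hdl_mgdl=55.0))
        assert c.central_obesity and c.n_components == 1 and not c.mets

    def test_female_hdl_threshold_is_50(self):
        assert component_flags(make_record(sex="female", wc=70, hdl_mgdl=49.9)).low_hdl
        assert not component_flags(make_record(sex="female", wc=70, hdl_mgdl=50.0)).low_hdl

    @pytest.mark.parametrize("sbp, dbp, flag", [(130, 80, True), (120, 85, True), (129.9, 84.9, False)])
    def test_bp_thresholds(self, sbp, dbp, flag):
        assert component_flags(make_record(sbp=sbp, dbp=dbp)).elevated_bp is flag

    def test_fpg_threshold_100(self):
        assert component_flags(make_record(fpg_mgdl=100.0)).elevated_fpg
        assert not component_flags(make_record(fpg_mgdl=99.9)).elevated_fpg


class TestTherapyOverrides:
    def test_antihypertensive_overrides_normal_bp(self):
        c = component_flags(make_record(sbp=120, dbp=80, antihypertensive_med=True))
        assert c.elevated_bp

    @pytest.mark.parametrize("flag", ["antidiabetic_med", "diabetes_history"])
    def test_glucose_overrides(self, flag):
        c = component_flags(make_record(fpg_mgdl=90.0, **{flag: True}))
        assert c.elevated_fpg

    def test_no_override_for_lipids(self):
        # medication flags must not touch the TG/HDL components
        c = component_flags(
            make_record(tg_mgdl=100, hdl_mgdl=60, antihypertensive_med=True,
                        antidiabetic_med=True, diabetes_history=True)
        )
        assert not c.elevated_tg and not c.low_hdl


def test_three_of_five_rule():
    c = component_flags(make_record(wc=95, tg_mgdl=160, hdl_mgdl=39))
    assert c.n_components == 3 and c.mets
    c = component_flags(make_record(wc=95, tg_mgdl=160))
    assert c.n_components == 2 and not c.mets


def test_risk_monotonicity():
    """Raising any analyte across its threshold never lowers the count."""
    base = make_record()
    n0 = component_flags(base).n_components
    worse = dict(wc=95.0, tg=200.0 / MG_DL_PER_MMOL_L["TG"],
                 hdl=30.0 / MG_DL_PER_MMOL_L["HDL"], sbp=150.0,
                 fpg=120.0 / MG_DL_PER_MMOL_L["glucose"])
    for field_name, value in worse.items():
        record = dataclasses.replace(base, **{field_name: value})
        assert component_flags(record).n_components >= n0


def test_diagnosis_invariant_to_supplied_unit():
    """A value entered in mg/dL and converted to storage units must flag
    identically to the same value entered in mmol/L (round-trip jitter at
    the exact threshold must not flip a component)."""
    for tg_mgdl in (149.999, 150.0, 150.001):
        direct = make_record(tg_mgdl=tg_mgdl)
        # double round trip mg/dL -> mmol/L -> mg/dL -> mmol/L
        jittered = dataclasses.replace(
            direct, tg=(direct.tg * MG_DL_PER_MMOL_L["TG"]) / MG_DL_PER_MMOL_L["TG"]
        )
        assert component_flags(direct).elevated_tg == component_flags(jittered).elevated_tg


def test_age_band_labels():
    assert age_band_label(45) == "45-54"
    assert age_band_label(54.9) == "45-54"
    assert age_band_label(55.0) == "55-64"
    assert age_band_label(74.99) == "65-74"
    assert age_band_label(75.0) == ">=75"
    assert age_band_label(98.0) == ">=75"


class TestCohortDiagnosis:
    def test_published_count_arithmetic(self):
        """Prevalence percentages reproduce the printed cohort counts:
        1331/4340 male and 2629/5117 female cases give 30.67%, 51.38% and
        41.87% overall."""
        rows = []
        for sex, n, n_mets in (("male", 4340, 1331), ("female", 5117, 2629)):
            for i in range(n):
                rows.append({"sex": sex, "age": 60.0, "mets": i < n_mets})
        frame = pd.DataFrame(rows)
        # construct minimal records realising those counts
        cohort = pd.DataFrame(
            {
                "sex": frame["sex"],
                "age": frame["age"],
                "wc": np.where(frame["mets"], 120.0, 70.0),
                "tg": np.where(frame["mets"], 3.0, 1.0),
                "hdl": np.where(frame["mets"], 0.8, 2.0),
                "fpg": 5.0,
                "sbp": 120.0,
                "dbp": 80.0,
                "antihypertensive_med": False,
                "antidiabetic_med": False,
                "diabetes_history": False,
            }
        )
        _, prevalence = diagnose_cohort(cohort)
        table = prevalence.set_index("stratum")["prevalence_percent"]
        assert table["overall"] == 41.87
        assert table["male"] == 30.67
        assert table["female"] == 51.38

    def test_degenerate_cohorts(self):
        base = dict(age=60.0, sbp=120.0, dbp=80.0, antihypertensive_med=False,
                    antidiabetic_med=False, diabetes_history=False, fpg=5.0)
        none_ill = pd.DataFrame([dict(sex="male", wc=70.0, tg=1.0, hdl=2.0, **base)] * 5)
        _, prev = diagnose_cohort(none_ill)
        assert prev.set_index("stratum").loc["overall", "prevalence_percent"] == 0.0
        all_ill = pd.DataFrame(
            [dict(sex="female", wc=120.0, tg=3.0, hdl=0.5, **{**base, "sbp": 160.0, "fpg": 8.0})]
        )
        _, prev = diagnose_cohort(all_ill)
        assert prev.set_index("stratum").loc["overall", "prevalence_percent"] == 100.0

    def test_empty_cohort_rejected(self):
        with pytest.raises(ValueError):
            diagnose_cohort(pd.DataFrame(columns=["sex", "age"]))

    def test_flag_count_invariant(self, cohort10k):
        flags = components_frame(cohort10k)
        assert (flags["n_components"] == flags[list(COMPONENT_NAMES)].sum(axis=1)).all()
        assert (flags["mets"] == (flags["n_components"] >= 3)).all()
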