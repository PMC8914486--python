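"""HCRU and cost aggregation: MF-relatedness, admission grouping, CPI,
accounting identities."""

import numpy as np
import pandas as pd
import pytest

from mfclaims import hcru_cost as hc
from mfclaims.claims_model import ClaimsBundle
from mfclaims.hcru_cost import (POST6, PRE6, WindowSpec, adjust_cpi,
                                group_inpatient_admissions, is_mf_related,
                                load_cpi_table, summarize_costs, summarize_hcru)

IDX = pd.Timestamp("2016-01-04")


def _med(rows):
    """rows: (offset, end_offset, dx, setting, plan_cents, patient_cents)"""
    return pd.DataFrame([{
        "claim_id": f"M{i}", "patient_id": "P1",
        "service_date": IDX + pd.Timedelta(days=a),
        "end_date": IDX + pd.Timedelta(days=b),
        "dx_codes": dx, "dx_systems": "|".join(["ICD10"] * len(dx.split("|"))),
        "procedure_codes": "", "setting": setting, "diagnostic_only": False,
        "plan_paid_cents": plan, "patient_paid_cents": pat}
        for i, (a, b, dx, setting, plan, pat) in enumerate(rows)])


class TestMfRelated:
    def test_mf_dx_any_position(self):
        claim = {"dx_codes": "R5383|I10|D474"}
        assert is_mf_related(claim)

    def test_rux_fill_is_mf_related(self):
        assert is_mf_related({"agent": "ruxolitinib"})

    def test_hypertension_only_is_not(self):
        assert not is_mf_related({"dx_codes": "I10"})
        assert not is_mf_related({"agent": "atorvastatin"})


class TestAdmissionGrouping:
    def test_abutting_claims_merge(self):
        claims = _med([(0, 3, "D474", "inpatient", 100, 0),
                       (3, 5, "D474", "inpatient", 200, 50)])
        adm = group_inpatient_admissions(claims)
        assert len(adm) == 1
        assert adm.iloc[0]["admit_date"] == IDX
        assert adm.iloc[0]["discharge_date"] == IDX + pd.Timedelta(days=5)
        assert adm.iloc[0]["paid_cents"] == 350

    def test_next_day_abutment_merges(self):
        claims = _med([(0, 3, "D474", "inpatient", 0, 0),
                       (4, 6, "D474", "inpatient", 0, 0)])
        assert len(group_inpatient_admissions(claims)) == 1

    def test_separated_claims_are_two_admissions(self):
        claims = _med([(0, 2, "D474", "inpatient", 0, 0),
                       (10, 11, "D474", "inpatient", 0, 0)])
        assert len(group_inpatient_admissions(claims)) == 2

    def test_empty_input(self):
        assert len(group_inpatient_admissions(_med([]).iloc[0:0])) == 0

    def test_vectorized_grouping_matches_per_patient(self, small_bundle):
        bundle, _ = small_bundle
        inp = bundle.medical_claims[bundle.medical_claims["setting"] == "inpatient"]
        fast = hc._admissions_all_patients(inp)
        slow_counts = {pid: len(group_inpatient_admissions(grp))
                       for pid, grp in inp.groupby("patient_id")}
        fast_counts = fast.groupby("patient_id").size().to_dict()
        assert fast_counts == slow_counts


class TestCpi:
    def test_identity_year(self):
        cpi = load_cpi_table()
        assert adjust_cpi(100.0, 2018, cpi) == pytest.approx(100.0)
        assert adjust_cpi(0.0, 2013, cpi) == 0.0

    def test_ratio_arithmetic(self):
        cpi = {2018: 110.0, 2015: 100.0}
        assert adjust_cpi(100.0, 2015, cpi) == pytest.approx(110.0)

    def test_missing_year_fatal_naming_year(self):
        with pytest.raises(KeyError, match="2003"):
            adjust_cpi(10.0, 2003, load_cpi_table())

    def test_all_ones_table_is_identity(self, small_bundle):
        bundle, _ = small_bundle
        from mfclaims.cohort_builder import apply_primary_selection
        members = apply_primary_selection(bundle).members
        ones = {y: 1.0 for y in range(2010, 2020)}
        real = load_cpi_table()
        a = summarize_costs(bundle, members, POST6, cpi=ones).per_patient
        b = bundle.medical_claims
        raw = ((b["plan_paid_cents"] + b["patient_paid_cents"])
               .groupby(b["patient_id"]).sum())
        # with a flat table the adjusted medical totals are the raw cents
        merged = a.set_index("patient_id")
        for pid in merged.index[:10]:
            assert merged.loc[pid, "medical"] <= raw.get(pid, 0)


def _one_patient_bundle():
    patients = pd.DataFrame([{"patient_id": "P1", "birth_year": 1950,
                              "sex": "male", "region": "South",
                              "insurance": "commercial", "death_date": pd.NaT}])
    enrollment = pd.DataFrame([{"patient_id": "P1",
                                "start_date": IDX - pd.Timedelta(days=400),
                                "end_date": IDX + pd.Timedelta(days=400),
                                "medical_benefit": True, "pharmacy_benefit": True}])
    med = _med([(10, 12, "D474", "inpatient", 90000, 10000)])
    rx = pd.DataFrame([{
        "claim_id": "P0", "patient_id": "P1",
        "fill_date": IDX + pd.Timedelta(days=5), "agent": "ruxolitinib",
        "strength_mg": 5.0, "quantity": 180.0, "days_supply": 30,
        "plan_paid_cents": 18000, "patient_paid_cents": 2000}])
    return ClaimsBundle(patients, enrollment, med, rx)


class TestCosts:
    def test_hand_computed_components(self):
        """$1,000 inpatient + $200 RUX fill: total 1,200; medical 1,000;
        pharmacy 200 (claims dated 2016, CPI-adjusted to 2018)."""
        bundle = _one_patient_bundle()
        members = pd.DataFrame([{"patient_id": "P1", "index_date": IDX}])
        flat = {y: 1.0 for y in range(2010, 2020)}
        summ = summarize_costs(bundle, members, POST6, cpi=flat)
        t = summ.table.set_index("component")
        assert t.loc["total", "mean"] == pytest.approx(1200.0)
        assert t.loc["medical", "mean"] == pytest.approx(1000.0)
        assert t.loc["inpatient", "mean"] == pytest.approx(1000.0)
        assert t.loc["pharmacy", "mean"] == pytest.approx(200.0)
        # with the real table, 2016 dollars inflate to 2018 dollars
        cpi = load_cpi_table()
        summ2 = summarize_costs(bundle, members, POST6, cpi=cpi)
        factor = cpi[2018] / cpi[2016]
        assert summ2.table.set_index("component").loc["total", "mean"] == \
            pytest.approx(1200.0 * factor, rel=1e-4)

    def test_zero_cost_patients_included_in_means(self):
        bundle = _one_patient_bundle()
        members = pd.DataFrame([{"patient_id": "P1", "index_date": IDX}])
        # a window with no claims still averages over the full cohort
        far = WindowSpec("far", 300, 350)
        summ = summarize_costs(bundle, members, far)
        assert summ.table.set_index("component").loc["total", "mean"] == 0.0
        assert summ.n_patients == 1

    def test_accounting_identity_exact_cents(self, pipeline_small):
        for (window, scope), summ in pipeline_small.costs.items():
            pp = summ.per_patient
            assert (pp["total"] == pp["medical"] + pp["pharmacy"]).all()
            assert (pp["medical"] == pp[list(hc.COST_COMPONENTS)].sum(axis=1)).all()

    def test_scope_nesting(self, pipeline_small):
        for window in ("pre6", "post6"):
            allc = pipeline_small.costs[(window, "all_cause")].per_patient.set_index("patient_id")
            mfc = pipeline_small.costs[(window, "mf_related")].per_patient.set_index("patient_id")
            assert (mfc["total"] <= allc["total"].reindex(mfc.index)).all()


class TestHcru:
    def test_no_claims_contributes_zeros(self):
        bundle = _one_patient_bundle()
        members = pd.DataFrame([{"patient_id": "P1", "index_date": IDX}])
        summ = summarize_hcru(bundle, members, PRE6)
        assert (summ.table["n_ge1"] == 0).all()

    def test_two_office_visits_counted(self):
        bundle = _one_patient_bundle()
        extra = _med([(20, 20, "I10", "office", 0, 0), (40, 40, "I10", "office", 0, 0)])
        extra["claim_id"] = ["MO1", "MO2"]
        bundle.medical_claims = pd.concat([bundle.medical_claims, extra],
                                          ignore_index=True)
        members = pd.DataFrame([{"patient_id": "P1", "index_date": IDX}])
        summ = summarize_hcru(bundle, members, POST6)
        t = summ.table.set_index("category")
        assert t.loc["office", "n_ge1"] == 1
        assert t.loc["office", "mean_count"] == 2.0
        assert t.loc["inpatient_admissions", "n_ge1"] == 1

    def test_boundary_admission_counted_by_admit_date(self):
        """A stay admitted pre-index and discharged post-index counts in
        the pre window only."""
        bundle = _one_patient_bundle()
        stay = _med([(-2, 3, "D474", "inpatient", 0, 0)])
        stay["claim_id"] = "MB1"
        bundle.medical_claims = stay
        members = pd.DataFrame([{"patient_id": "P1", "index_date": IDX}])
        pre = summarize_hcru(bundle, members, PRE6).table.set_index("category")
        post = summarize_hcru(bundle, members, POST6).table.set_index("category")
        assert pre.loc["inpatient_admissions", "n_ge1"] == 1
        assert post.loc["inpatient_admissions", "n_ge1"] == 0

    def test_mf_scope_counts_nested(self, pipeline_small):
        for window in ("pre6", "post6"):
            allc = pipeline_small.hcru[(window, "all_cause")].per_patient.set_index("patient_id")
            mfc = pipeline_small.hcru[(window, "mf_related")].per_patient.set_index("patient_id")
            for cat in ("office", "outpatient", "ed"):
                assert (mfc[cat] <= allc[cat].reindex(mfc.index)).all()
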