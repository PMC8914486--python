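"""Cohort selection: index-date rules, enrollment coverage, attrition."""

import numpy as np
import pandas as pd
import pytest

import mfclaims as m
from mfclaims import cohort_builder as cb
from mfclaims.claims_model import join_codes

CFG = cb.SelectionConfig()


def _med_claims(rows):
    """rows: (day offset from 2016-01-04, codes, diagnostic_only)"""
    base = pd.Timestamp("2016-01-04")
    out = []
    for i, (off, codes, diag) in enumerate(rows):
        out.append({
            "claim_id": f"M{i}", "patient_id": "P1",
            "service_date": base + pd.Timedelta(days=off),
            "end_date": base + pd.Timedelta(days=off),
            "dx_codes": join_codes(codes),
            "dx_systems": join_codes(["ICD10"] * len(codes)),
            "procedure_codes": "", "setting": "office",
            "diagnostic_only": diag, "plan_paid_cents": 0, "patient_paid_cents": 0,
        })
    return pd.DataFrame(out)


class TestIndexMfDate:
    def test_thirty_day_separation_qualifies(self):
        claims = _med_claims([(0, ["D474"], False), (30, ["D474"], False)])
        hit = cb.find_index_mf_date(claims, CFG)
        assert hit is not None
        assert hit[0] == pd.Timestamp("2016-01-04")
        assert hit[1] == "primary_mf"

    def test_twenty_nine_day_separation_fails(self):
        claims = _med_claims([(0, ["D474"], False), (29, ["D474"], False)])
        assert cb.find_index_mf_date(claims, CFG) is None

    def test_single_claim_fails(self):
        claims = _med_claims([(0, ["D474"], False)])
        assert cb.find_index_mf_date(claims, CFG) is None

    def test_diagnostic_only_claims_excluded(self):
        claims = _med_claims([(0, ["D474"], True), (40, ["D474"], False),
                              (80, ["D474"], False)])
        hit = cb.find_index_mf_date(claims, CFG)
        assert hit[0] == pd.Timestamp("2016-01-04") + pd.Timedelta(days=40)

    def test_any_dx_position_counts(self):
        claims = _med_claims([(0, ["R5383", "I10", "D7581"], False),
                              (45, ["R5383", "D7581"], False)])
        hit = cb.find_index_mf_date(claims, CFG)
        assert hit == (pd.Timestamp("2016-01-04"), "secondary_mf")

    def test_primary_wins_over_secondary(self):
        claims = _med_claims([(0, ["D7581"], False), (40, ["D474"], False)])
        assert cb.find_index_mf_date(claims, CFG)[1] == "primary_mf"

    def test_outside_identification_window_ignored(self):
        claims = _med_claims([(0, ["D474"], False), (40, ["D474"], False)])
        early = claims.copy()
        early["service_date"] = pd.Timestamp("2011-06-01")  # before 2012-01-01
        assert cb.find_index_mf_date(early, CFG) is None


class TestEnrollment:
    def _spans(self, rows):
        return pd.DataFrame([{
            "patient_id": "P1", "start_date": pd.Timestamp(a),
            "end_date": pd.Timestamp(b), "medical_benefit": med,
            "pharmacy_benefit": pha} for a, b, med, pha in rows])

    def test_single_covering_span(self):
        spans = self._spans([("2015-01-01", "2017-01-01", True, True)])
        assert cb.continuously_enrolled(spans, "P1", pd.Timestamp("2015-06-01"),
                                        pd.Timestamp("2016-06-01"))

    def test_one_day_gap_fails(self):
        spans = self._spans([("2015-01-01", "2015-12-30", True, True),
                             ("2016-01-01", "2017-01-01", True, True)])
        assert not cb.continuously_enrolled(spans, "P1", pd.Timestamp("2015-06-01"),
                                            pd.Timestamp("2016-06-01"))

    def test_abutting_spans_cover(self):
        spans = self._spans([("2015-01-01", "2015-12-31", True, True),
                             ("2016-01-01", "2017-01-01", True, True)])
        assert cb.continuously_enrolled(spans, "P1", pd.Timestamp("2015-06-01"),
                                        pd.Timestamp("2016-06-01"))

    def test_missing_pharmacy_benefit_fails(self):
        spans = self._spans([("2015-01-01", "2017-01-01", True, False)])
        assert not cb.continuously_enrolled(spans, "P1", pd.Timestamp("2015-06-01"),
                                            pd.Timestamp("2016-06-01"))


class TestRuxIndex:
    COLS = ["claim_id", "patient_id", "fill_date", "agent", "strength_mg",
            "quantity", "days_supply", "plan_paid_cents", "patient_paid_cents"]

    def _fills(self, offsets, agent="ruxolitinib"):
        base = pd.Timestamp("2016-01-04")
        rows = [{
            "claim_id": f"P{i}", "patient_id": "P1",
            "fill_date": base + pd.Timedelta(days=o), "agent": agent,
            "strength_mg": 5.0, "quantity": 60.0, "days_supply": 30,
            "plan_paid_cents": 0, "patient_paid_cents": 0}
            for i, o in enumerate(offsets)]
        return pd.DataFrame(rows, columns=self.COLS)

    def test_fill_before_index_excluded(self):
        idx = pd.Timestamp("2016-01-04")
        fills = self._fills([-5, 10])
        assert cb.find_index_rux_date(fills, idx, CFG) == idx + pd.Timedelta(days=10)

    def test_fill_on_index_counts(self):
        idx = pd.Timestamp("2016-01-04")
        assert cb.find_index_rux_date(self._fills([0]), idx, CFG) == idx

    def test_no_fills_absent(self):
        idx = pd.Timestamp("2016-01-04")
        assert cb.find_index_rux_date(self._fills([], ), idx, CFG) is None
        assert cb.find_index_rux_date(self._fills([5], agent="hydroxyurea"),
                                      idx, CFG) is None


class TestSelectionPipelines:
    def test_attrition_monotone_and_final_count(self, small_bundle):
        bundle, _ = small_bundle
        res = cb.apply_primary_selection(bundle)
        n = res.attrition["n_remaining"].to_numpy()
        assert (np.diff(n) <= 0).all()
        assert n[-1] == len(res.members)

    def test_age_seventeen_removed_at_age_step(self, small_bundle):
        bundle, _ = small_bundle
        b = bundle.copy()
        before = cb.apply_primary_selection(b)
        surv = before.members["patient_id"].iloc[0]
        idx_year = before.members["index_date"].iloc[0].year
        b.patients.loc[b.patients["patient_id"] == surv, "birth_year"] = idx_year - 17
        after = cb.apply_primary_selection(b)
        assert surv not in set(after.members["patient_id"])
        a0 = before.attrition.set_index("criterion")["n_remaining"]
        a1 = after.attrition.set_index("criterion")["n_remaining"]
        assert a1["mf_claims_30d_apart"] == a0["mf_claims_30d_apart"]
        assert a1["age_ge_18"] == a0["age_ge_18"] - 1

    def test_disenrollment_100d_post_removed_at_enrollment_step(self, small_bundle):
        bundle, _ = small_bundle
        b = bundle.copy()
        before = cb.apply_primary_selection(b)
        surv = before.members.iloc[0]
        cut = surv["index_date"] + pd.Timedelta(days=100)
        mask = b.enrollment["patient_id"] == surv["patient_id"]
        b.enrollment.loc[mask, "end_date"] = b.enrollment.loc[mask, "end_date"].clip(upper=cut)
        after = cb.apply_primary_selection(b)
        assert surv["patient_id"] not in set(after.members["patient_id"])

    def test_pregnancy_code_excludes(self, small_bundle):
        bundle, _ = small_bundle
        b = bundle.copy()
        before = cb.apply_primary_selection(b)
        surv = before.members.iloc[0]
        extra = b.medical_claims.iloc[0].copy()
        extra["claim_id"] = "MPREG"
        extra["patient_id"] = surv["patient_id"]
        extra["service_date"] = extra["end_date"] = surv["index_date"] + pd.Timedelta(days=50)
        extra["dx_codes"], extra["dx_systems"] = "Z331", "ICD10"
        extra["diagnostic_only"] = False
        b.medical_claims = pd.concat([b.medical_claims, extra.to_frame().T],
                                     ignore_index=True)
        for c in ("service_date", "end_date"):
            b.medical_claims[c] = pd.to_datetime(b.medical_claims[c])
        after = cb.apply_primary_selection(b)
        assert surv["patient_id"] not in set(after.members["patient_id"])

    def test_subgroup_subset_and_index_ordering(self, small_bundle):
        bundle, _ = small_bundle
        primary = cb.apply_primary_selection(bundle)
        sub = cb.apply_subgroup_selection(bundle, primary)
        cand = set(primary.mf_candidates["patient_id"])
        assert set(sub.members["patient_id"]) <= cand
        assert (sub.members["index_date"] >= sub.members["index_mf_date"]).all()

    def test_subgroup_short_post_rux_enrollment_excluded(self, small_bundle):
        bundle, _ = small_bundle
        b = bundle.copy()
        sub_before = cb.apply_subgroup_selection(b)
        assert len(sub_before.members), "fixture should contain RUX patients"
        surv = sub_before.members.iloc[0]
        cut = surv["index_date"] + pd.Timedelta(days=60)
        mask = b.enrollment["patient_id"] == surv["patient_id"]
        b.enrollment.loc[mask, "end_date"] = b.enrollment.loc[mask, "end_date"].clip(upper=cut)
        sub_after = cb.apply_subgroup_selection(b)
        assert surv["patient_id"] not in set(sub_after.members["patient_id"])

    def test_row_order_invariance(self, small_bundle):
        """Shuffling claim-table rows changes neither membership nor indices."""
        bundle, _ = small_bundle
        b = bundle.copy()
        rng = np.random.default_rng(0)
        b.medical_claims = b.medical_claims.sample(frac=1, random_state=1).reset_index(drop=True)
        b.pharmacy_claims = b.pharmacy_claims.sample(frac=1, random_state=2).reset_index(drop=True)
        b.enrollment = b.enrollment.sample(frac=1, random_state=3).reset_index(drop=True)
        a = cb.apply_primary_selection(bundle).members.sort_values("patient_id")
        c = cb.apply_primary_selection(b).members.sort_values("patient_id")
        pd.testing.assert_frame_equal(a.reset_index(drop=True), c.reset_index(drop=True))
        sa = cb.apply_subgroup_selection(bundle).members.sort_values("patient_id")
        sc_ = cb.apply_subgroup_selection(b).members.sort_values("patient_id")
        pd.testing.assert_frame_equal(sa.reset_index(drop=True), sc_.reset_index(drop=True))
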