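"""Index-date identification and cohort selection with stepwise attrition.

Implements the two-stage design of the myelofibrosis (MF) claims study:

* **primary cohort** — adults with ≥2 non-diagnostic medical claims
  carrying primary (ICD-9 238.76 / ICD-10 D47.4) or secondary
  (289.83 / D75.81) MF diagnosis codes in any position, ≥30 days apart,
  inside the identification window; continuously enrolled with medical
  and pharmacy benefits for 12 months before and 6 months after the
  index MF date (the earliest qualifying MF claim); no pregnancy or
  clinical-trial evidence around the index.
* **RUX subgroup** — primary-criterion patients with a ruxolitinib fill
  on or after the index MF date; the index RUX date is that first fill,
  with 3-month pre / 6-month post enrollment and the same
  pregnancy/trial screens applied around it.

Window arithmetic is day-granular on closed intervals: 12 months = 365
days, 6 months = 183 days, 3 months = 91 days; the pre-index window is
``[index - L, index - 1]`` and the post-index window ``[index,
index + 182]`` (the index day belongs to the post period).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .claims_model import ClaimsBundle, normalize_code, split_codes

# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

PRIMARY_MF_CODES = frozenset({"23876", "D474"})
SECONDARY_MF_CODES = frozenset({"28983", "D7581"})
MF_CODES = PRIMARY_MF_CODES | SECONDARY_MF_CODES

# clinical-trial participation evidence
TRIAL_DX_CODES = frozenset({"V707"})
TRIAL_PROC_CODES = frozenset({"S9988", "S9990", "S9991", "S9992", "S9994", "S9996"})

# pregnancy evidence is a configurable scan; default list holds the
# common "pregnancy state" codes the generator uses as sentinels
PREGNANCY_CODES = frozenset({"Z331", "V222"})


def _norm_set(codes) -> frozenset:
    return frozenset(normalize_code(c) for c in codes)


@dataclass(frozen=True)
class SelectionConfig:
    primary_mf_codes: frozenset = PRIMARY_MF_CODES
    secondary_mf_codes: frozenset = SECONDARY_MF_CODES
    min_claim_separation_days: int = 30
    identification_start: pd.Timestamp = pd.Timestamp("2012-01-01")
    identification_end: pd.Timestamp = pd.Timestamp("2018-06-30")
    study_cutoff: pd.Timestamp = pd.Timestamp("2018-06-30")
    pre_index_days_primary: int = 365   # 12 months
    pre_index_days_subgroup: int = 91   # 3 months
    post_index_days: int = 183          # 6 months
    min_age: int = 18
    pregnancy_codes: frozenset = PREGNANCY_CODES
    trial_dx_codes: frozenset = TRIAL_DX_CODES
    trial_proc_codes: frozenset = TRIAL_PROC_CODES
    rux_agent: str = "ruxolitinib"

    @property
    def mf_codes(self) -> frozenset:
        return self.primary_mf_codes | self.secondary_mf_codes


@dataclass
class CohortResult:
    """Selected members plus the stepwise attrition table.

    ``members`` columns: ``patient_id``, ``index_date``,
    ``diagnosis_type`` (primary_mf/secondary_mf), and for the subgroup
    additionally ``index_mf_date``. ``attrition`` columns:
    ``criterion``, ``n_remaining``.
    """

    members: pd.DataFrame
    attrition: pd.DataFrame
    # criterion-1 survivors (MF-claims rule) with their index dates; the
    # subgroup stage starts from these
    mf_candidates: pd.DataFrame = field(default_factory=pd.DataFrame)


# ---------------------------------------------------------------------------
# Index-date identification
# ---------------------------------------------------------------------------


def _claim_codes(row) -> list[str]:
    return split_codes(row)


def find_index_mf_date(
    medical_claims: pd.DataFrame, config: SelectionConfig = SelectionConfig()
) -> tuple[pd.Timestamp, str] | None:
    """Earliest qualifying MF claim date for one patient's medical claims.

    Qualifying claims are non-diagnostic, dated inside the
    identification window, and carry an MF code in any position. The
    patient qualifies only if two such claims exist ≥30 days apart
    (``d2 - d1 >= 30``). Returns ``(index_date, diagnosis_type)`` or
    ``None``; diagnosis_type is ``primary_mf`` if any qualifying claim
    carries a primary-MF code, else ``secondary_mf``.
    """
    df = medical_claims
    if not len(df):
        return None
    in_window = (df["service_date"] >= config.identification_start) & (
        df["service_date"] <= config.identification_end
    )
    cand = df[in_window & ~df["diagnostic_only"]]
    if not len(cand):
        return None
    has_mf = cand["dx_codes"].map(
        lambda v: any(c in config.mf_codes for c in split_codes(v))
    )
    cand = cand[has_mf]
    if not len(cand):
        return None
    dates = cand["service_date"].sort_values()
    if (dates.iloc[-1] - dates.iloc[0]).days < config.min_claim_separation_days:
        return None
    any_primary = cand["dx_codes"].map(
        lambda v: any(c in config.primary_mf_codes for c in split_codes(v))
    ).any()
    dtype = "primary_mf" if any_primary else "secondary_mf"
    return dates.iloc[0], dtype


def find_index_rux_date(
    pharmacy_claims: pd.DataFrame,
    index_mf_date: pd.Timestamp,
    config: SelectionConfig = SelectionConfig(),
) -> pd.Timestamp | None:
    """Earliest RUX fill on or after the index MF date, else ``None``."""
    rx = pharmacy_claims
    fills = rx[(rx["agent"] == config.rux_agent) & (rx["fill_date"] >= index_mf_date)]
    if not len(fills):
        return None
    return fills["fill_date"].min()


# ---------------------------------------------------------------------------
# Enrollment coverage
# ---------------------------------------------------------------------------


def _spans_cover(spans: pd.DataFrame, window_start, window_end) -> bool:
    """Do the (benefit-filtered) spans jointly cover every day of the window?"""
    if not len(spans):
        return False
    spans = spans.sort_values("start_date")
    cursor = window_start
    one_day = pd.Timedelta(days=1)
    for start, end in zip(spans["start_date"], spans["end_date"]):
        if end < cursor - one_day:
            continue
        if start > cursor:
            return False
        cursor = end + one_day
        if cursor > window_end:
            return True
    return cursor > window_end


def continuously_enrolled(
    enrollment: pd.DataFrame,
    patient_id: str,
    window_start: pd.Timestamp,
    window_end: pd.Timestamp,
    require_medical: bool = True,
    require_pharmacy: bool = True,
) -> bool:
    """True iff every day in ``[window_start, window_end]`` is covered by
    enrollment spans with the required benefit flags. Abutting spans
    (one ends day d, the next starts day d+1) jointly cover."""
    spans = enrollment[enrollment["patient_id"] == patient_id]
    if require_medical:
        spans = spans[spans["medical_benefit"]]
    if require_pharmacy:
        spans = spans[spans["pharmacy_benefit"]]
    return _spans_cover(spans, window_start, window_end)


# ---------------------------------------------------------------------------
# Exclusion-code scans
# ---------------------------------------------------------------------------


def _has_codes_in_window(
    medical_claims: pd.DataFrame,
    dx_codes: frozenset,
    proc_codes: frozenset,
    window_start: pd.Timestamp,
    window_end: pd.Timestamp,
) -> bool:
    df = medical_claims
    df = df[(df["service_date"] >= window_start) & (df["service_date"] <= window_end)]
    if not len(df):
        return False
    if dx_codes:
        if df["dx_codes"].map(
            lambda v: any(c in dx_codes for c in split_codes(v))
        ).any():
            return True
    if proc_codes:
        if df["procedure_codes"].map(
            lambda v: any(c in proc_codes for c in split_codes(v))
        ).any():
            return True
    return False


# ---------------------------------------------------------------------------
# Selection pipelines
# ---------------------------------------------------------------------------


def _age_at_year(birth_year: int, index_year: int) -> int:
    # year-granular birth data: age as of the index year
    return index_year - birth_year


def apply_primary_selection(
    bundle: ClaimsBundle, config: SelectionConfig = SelectionConfig()
) -> CohortResult:
    """Apply the primary-analysis criteria in order, recording attrition.

    Criteria: (1) MF-claims rule, (2) age ≥18 at index year,
    (3) continuous enrollment over the 12-month pre and 6-month post
    windows, (4) no pregnancy evidence, (5) no trial evidence.
    """
    med_by_pid = dict(tuple(bundle.medical_claims.groupby("patient_id", sort=False)))
    empty_med = bundle.medical_claims.iloc[0:0]
    benefit_spans = bundle.enrollment[
        bundle.enrollment["medical_benefit"] & bundle.enrollment["pharmacy_benefit"]]
    spans_by_pid = dict(tuple(benefit_spans.groupby("patient_id", sort=False)))
    empty_spans = benefit_spans.iloc[0:0]
    attrition: list[tuple[str, int]] = [("all_patients", bundle.n_patients)]

    # (1) MF claims rule
    rows = []
    for pid in bundle.patients["patient_id"]:
        hit = find_index_mf_date(med_by_pid.get(pid, empty_med), config)
        if hit is not None:
            rows.append({"patient_id": pid, "index_date": hit[0], "diagnosis_type": hit[1]})
    cur = pd.DataFrame(rows, columns=["patient_id", "index_date", "diagnosis_type"])
    candidates = cur.copy()
    attrition.append(("mf_claims_30d_apart", len(cur)))

    # (2) age
    by = bundle.patients.set_index("patient_id")["birth_year"]
    if len(cur):
        age = cur["index_date"].dt.year - cur["patient_id"].map(by)
        cur = cur[age >= config.min_age]
    attrition.append(("age_ge_18", len(cur)))

    # (3) continuous enrollment
    keep = []
    for _, r in cur.iterrows():
        idx = r["index_date"]
        spans = spans_by_pid.get(r["patient_id"], empty_spans)
        pre_ok = _spans_cover(
            spans,
            idx - pd.Timedelta(days=config.pre_index_days_primary),
            idx - pd.Timedelta(days=1),
        )
        post_ok = _spans_cover(
            spans, idx, idx + pd.Timedelta(days=config.post_index_days - 1))
        keep.append(pre_ok and post_ok)
    cur = cur[pd.Series(keep, index=cur.index, dtype=bool)] if len(cur) else cur
    attrition.append(("continuous_enrollment", len(cur)))

    # (4) pregnancy, (5) trial — scan pre+post windows
    for label, dx, proc in (
        ("no_pregnancy", config.pregnancy_codes, frozenset()),
        ("no_trial_participation", config.trial_dx_codes, config.trial_proc_codes),
    ):
        keep = []
        for _, r in cur.iterrows():
            idx = r["index_date"]
            hit = _has_codes_in_window(
                med_by_pid.get(r["patient_id"], empty_med), dx, proc,
                idx - pd.Timedelta(days=config.pre_index_days_primary),
                idx + pd.Timedelta(days=config.post_index_days - 1),
            )
            keep.append(not hit)
        cur = cur[pd.Series(keep, index=cur.index, dtype=bool)] if len(cur) else cur
        attrition.append((label, len(cur)))

    att = pd.DataFrame(attrition, columns=["criterion", "n_remaining"])
    return CohortResult(cur.reset_index(drop=True), att, candidates)


def apply_subgroup_selection(
    bundle: ClaimsBundle,
    primary: CohortResult | None = None,
    config: SelectionConfig = SelectionConfig(),
) -> CohortResult:
    """Select the RUX-treated subgroup, anchored on the index RUX date.

    Starts from the primary analysis' MF-claims-criterion survivors
    (recomputed if ``primary`` is not supplied); members carry
    ``index_date`` = index RUX date and retain ``index_mf_date``.
    """
    if primary is None or primary.mf_candidates is None or not len(primary.mf_candidates):
        primary = apply_primary_selection(bundle, config)
    cand = primary.mf_candidates.copy()
    attrition: list[tuple[str, int]] = [("mf_claims_30d_apart", len(cand))]

    rx_by_pid = dict(tuple(bundle.pharmacy_claims.groupby("patient_id", sort=False)))
    med_by_pid = dict(tuple(bundle.medical_claims.groupby("patient_id", sort=False)))
    empty_rx = bundle.pharmacy_claims.iloc[0:0]
    empty_med = bundle.medical_claims.iloc[0:0]
    benefit_spans = bundle.enrollment[
        bundle.enrollment["medical_benefit"] & bundle.enrollment["pharmacy_benefit"]]
    spans_by_pid = dict(tuple(benefit_spans.groupby("patient_id", sort=False)))
    empty_spans = benefit_spans.iloc[0:0]

    # (2) ≥1 RUX fill on/after index MF
    rows = []
    for _, r in cand.iterrows():
        rux = find_index_rux_date(rx_by_pid.get(r["patient_id"], empty_rx),
                                  r["index_date"], config)
        if rux is not None:
            rows.append({
                "patient_id": r["patient_id"],
                "index_date": rux,
                "diagnosis_type": r["diagnosis_type"],
                "index_mf_date": r["index_date"],
            })
    cur = pd.DataFrame(rows, columns=["patient_id", "index_date",
                                      "diagnosis_type", "index_mf_date"])
    attrition.append(("rux_fill_on_or_after_index", len(cur)))

    # (3) age ≥18 as of index MF year
    by = bundle.patients.set_index("patient_id")["birth_year"]
    if len(cur):
        age = cur["index_mf_date"].dt.year - cur["patient_id"].map(by)
        cur = cur[age >= config.min_age]
    attrition.append(("age_ge_18", len(cur)))

    # (4) enrollment around index RUX
    keep = []
    for _, r in cur.iterrows():
        rux = r["index_date"]
        spans = spans_by_pid.get(r["patient_id"], empty_spans)
        pre_ok = _spans_cover(
            spans,
            rux - pd.Timedelta(days=config.pre_index_days_subgroup),
            rux - pd.Timedelta(days=1),
        )
        post_ok = _spans_cover(
            spans, rux, rux + pd.Timedelta(days=config.post_index_days - 1))
        keep.append(pre_ok and post_ok)
    cur = cur[pd.Series(keep, index=cur.index, dtype=bool)] if len(cur) else cur
    attrition.append(("continuous_enrollment", len(cur)))

    # (5)/(6) pregnancy & trial around index RUX
    for label, dx, proc in (
        ("no_pregnancy", config.pregnancy_codes, frozenset()),
        ("no_trial_participation", config.trial_dx_codes, config.trial_proc_codes),
    ):
        keep = []
        for _, r in cur.iterrows():
            rux = r["index_date"]
            hit = _has_codes_in_window(
                med_by_pid.get(r["patient_id"], empty_med), dx, proc,
                rux - pd.Timedelta(days=config.pre_index_days_subgroup),
                rux + pd.Timedelta(days=config.post_index_days - 1),
            )
            keep.append(not hit)
        cur = cur[pd.Series(keep, index=cur.index, dtype=bool)] if len(cur) else cur
        attrition.append((label, len(cur)))

    att = pd.DataFrame(attrition, columns=["criterion", "n_remaining"])
    return CohortResult(cur.reset_index(drop=True), att, primary.mf_candidates)


__all__ = [
    "CohortResult",
    "MF_CODES",
    "PRIMARY_MF_CODES",
    "SECONDARY_MF_CODES",
    "PREGNANCY_CODES",
    "SelectionConfig",
    "TRIAL_DX_CODES",
    "TRIAL_PROC_CODES",
    "apply_primary_selection",
    "apply_subgroup_selection",
    "continuously_enrolled",
    "find_index_mf_date",
    "find_index_rux_date",
]
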