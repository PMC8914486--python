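"""Health care resource utilization (HCRU) and cost aggregation.

All-cause and MF-related utilization — office and hospital-outpatient
("ambulatory") visits, emergency-department (ED) visits, and inpatient
admissions — and combined plan + patient paid costs are aggregated over
fixed windows anchored at each cohort member's index date (6-month
pre-index ``[index-183, index-1]`` and 6-month post-index
``[index, index+182]`` by default).

"MF-related" is a configured definition: a medical claim is MF-related
iff any diagnosis position carries an MF code; a pharmacy claim iff its
agent is on the MF treatment-agent list. Inpatient admissions are
counted at admission level: overlapping or date-abutting inpatient
claims merge into one stay, and an admission belongs to a window iff
its admit date does (its full cost counted there, avoiding double
counting across windows).

Costs are carried per claim in nominal-year cents and adjusted to 2018
US dollars with the annual medical-care component of the Consumer Price
Index at aggregation time; means and SDs are taken over *all* cohort
patients, zero-cost patients included.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .claims_model import ClaimsBundle, split_codes
from .cohort_builder import MF_CODES
from .comorbidity import _data_path
from .lot_engine import NCCN_MF_AGENTS, OTHER_SYSTEMIC_AGENTS

CPI_TABLE = "cpi_medical_care.csv"
REFERENCE_YEAR = 2018

HCRU_CATEGORIES = ("office", "outpatient", "ed", "inpatient_admissions")
COST_COMPONENTS = ("office", "outpatient", "ed", "inpatient", "other")


@dataclass(frozen=True)
class MfRelatedConfig:
    mf_dx_codes: frozenset = MF_CODES
    mf_agents: frozenset = NCCN_MF_AGENTS | OTHER_SYSTEMIC_AGENTS


@dataclass(frozen=True)
class WindowSpec:
    """Closed day window relative to the index date."""

    label: str
    start_offset: int  # e.g. -183 for the 6-month pre-index window
    end_offset: int    # e.g. -1

    def bounds(self, index_date: pd.Timestamp) -> tuple[pd.Timestamp, pd.Timestamp]:
        return (index_date + pd.Timedelta(days=self.start_offset),
                index_date + pd.Timedelta(days=self.end_offset))


PRE6 = WindowSpec("pre6", -183, -1)
POST6 = WindowSpec("post6", 0, 182)


def load_cpi_table(path=None) -> dict[int, float]:
    df = pd.read_csv(path or _data_path(CPI_TABLE))
    table = dict(zip(df["year"].astype(int), df["index"].astype(float)))
    if REFERENCE_YEAR not in table:
        raise ValueError(f"CPI table lacks reference year {REFERENCE_YEAR}")
    if any(v <= 0 for v in table.values()):
        raise ValueError("CPI index values must be positive")
    return table


def adjust_cpi(amount: float, service_year: int, cpi: dict[int, float]) -> float:
    """Inflate ``amount`` from ``service_year`` to 2018 dollars."""
    if service_year not in cpi:
        raise KeyError(f"CPI table has no entry for year {service_year}")
    return amount * cpi[REFERENCE_YEAR] / cpi[service_year]


def is_mf_related(claim: pd.Series | dict, config: MfRelatedConfig = MfRelatedConfig()) -> bool:
    """MF-related: any-position MF diagnosis (medical) or MF treatment
    agent (pharmacy)."""
    if "dx_codes" in claim:
        return any(c in config.mf_dx_codes for c in split_codes(claim["dx_codes"]))
    return claim["agent"] in config.mf_agents


def _medical_mask_mf(med: pd.DataFrame, config: MfRelatedConfig) -> pd.Series:
    return med["dx_codes"].map(
        lambda v: any(c in config.mf_dx_codes for c in split_codes(v)))


def group_inpatient_admissions(inpatient_claims: pd.DataFrame) -> pd.DataFrame:
    """Merge overlapping or date-abutting inpatient claims into stays.

    Returns ``admit_date``, ``discharge_date``, ``paid_cents`` (plan +
    patient, summed over merged claims), one row per admission."""
    if not len(inpatient_claims):
        return pd.DataFrame(columns=["admit_date", "discharge_date", "paid_cents"])
    out = []
    df = inpatient_claims.sort_values(["service_date", "end_date"])
    cur = None
    for _, row in df.iterrows():
        paid = int(row["plan_paid_cents"]) + int(row["patient_paid_cents"])
        if cur is not None and row["service_date"] <= cur["discharge_date"] + pd.Timedelta(days=1):
            cur["discharge_date"] = max(cur["discharge_date"], row["end_date"])
            cur["paid_cents"] += paid
        else:
            if cur is not None:
                out.append(cur)
            cur = {"admit_date": row["service_date"],
                   "discharge_date": row["end_date"], "paid_cents": paid}
    if cur is not None:
        out.append(cur)
    return pd.DataFrame(out, columns=["admit_date", "discharge_date", "paid_cents"])


@dataclass
class HcruSummary:
    window: str
    scope: str
    n_patients: int
    table: pd.DataFrame  # category, n_ge1, pct, mean_count
    per_patient: pd.DataFrame = field(repr=False, default_factory=pd.DataFrame)


def _admissions_all_patients(inpatient: pd.DataFrame) -> pd.DataFrame:
    """Vectorized multi-patient admission grouping; same merge rule as
    :func:`group_inpatient_admissions` (overlap or 1-day abutment)."""
    if not len(inpatient):
        return pd.DataFrame(columns=["patient_id", "admit_date"])
    inp = inpatient.sort_values(["patient_id", "service_date", "end_date"]).copy()
    inp["_cummax_end"] = inp.groupby("patient_id")["end_date"].cummax()
    prev_end = inp.groupby("patient_id")["_cummax_end"].shift()
    new_adm = prev_end.isna() | (inp["service_date"] > prev_end + pd.Timedelta(days=1))
    inp["_adm"] = new_adm.cumsum()
    adm = inp.groupby(["patient_id", "_adm"], sort=False).agg(
        admit_date=("service_date", "min")).reset_index()
    return adm[["patient_id", "admit_date"]]


def _in_window_mask(df: pd.DataFrame, date_col: str, window: WindowSpec) -> pd.Series:
    lo = df["index_date"] + pd.Timedelta(days=window.start_offset)
    hi = df["index_date"] + pd.Timedelta(days=window.end_offset)
    return (df[date_col] >= lo) & (df[date_col] <= hi)


def summarize_hcru(
    bundle: ClaimsBundle,
    members: pd.DataFrame,
    window: WindowSpec,
    scope: str = "all_cause",
    config: MfRelatedConfig = MfRelatedConfig(),
) -> HcruSummary:
    """Per-category utilization over ``window`` for every cohort member.

    ``scope`` is ``all_cause`` or ``mf_related``. Ambulatory visits are
    split office vs outpatient by claim setting, ED visits counted at
    claim level, inpatient at merged-admission level (an admission is in
    the window iff its admit date is)."""
    med = bundle.medical_claims
    if scope == "mf_related":
        med = med[_medical_mask_mf(med, config)]
    elif scope != "all_cause":
        raise ValueError(f"unknown scope {scope!r}")

    key = members[["patient_id", "index_date"]]
    mm = med.merge(key, on="patient_id", how="inner")
    mm = mm[_in_window_mask(mm, "service_date", window)]
    visit_counts = (mm[mm["setting"].isin(("office", "outpatient", "ed"))]
                    .groupby(["patient_id", "setting"], sort=False).size()
                    .unstack(fill_value=0))
    # admissions grouped over the patient's full inpatient history so a
    # stay split across the boundary is one admission, counted by admit date
    inp_all = med[med["setting"] == "inpatient"]
    adm = _admissions_all_patients(inp_all).merge(key, on="patient_id", how="inner")
    adm = adm[_in_window_mask(adm, "admit_date", window)]
    adm_counts = adm.groupby("patient_id", sort=False).size()

    per_patient = pd.DataFrame({"patient_id": members["patient_id"].values})
    for cat, setting in (("office", "office"), ("outpatient", "outpatient"), ("ed", "ed")):
        col = (visit_counts[setting] if setting in visit_counts.columns
               else pd.Series(dtype=int))
        per_patient[cat] = per_patient["patient_id"].map(col).fillna(0).astype(int)
    per_patient["inpatient_admissions"] = (
        per_patient["patient_id"].map(adm_counts).fillna(0).astype(int))
    n = len(members)
    rows = []
    for cat in HCRU_CATEGORIES:
        s = per_patient[cat]
        rows.append({
            "category": cat,
            "n_ge1": int((s >= 1).sum()),
            "pct": 100.0 * (s >= 1).mean() if n else np.nan,
            "mean_count": float(s.mean()) if n else np.nan,
        })
    return HcruSummary(window.label, scope, n, pd.DataFrame(rows), per_patient)


@dataclass
class CostSummary:
    window: str
    scope: str
    n_patients: int
    table: pd.DataFrame  # component, mean, sd (2018 USD per patient)
    per_patient: pd.DataFrame = field(repr=False, default_factory=pd.DataFrame)


def _adjusted_cents(df: pd.DataFrame, date_col: str, cpi: dict[int, float]) -> pd.Series:
    cents = df["plan_paid_cents"] + df["patient_paid_cents"]
    if not len(df):
        return cents
    factor = df[date_col].dt.year.map(
        lambda y: cpi[REFERENCE_YEAR] / cpi[y] if y in cpi else np.nan)
    if factor.isna().any():
        bad = sorted(df.loc[factor.isna(), date_col].dt.year.unique())
        raise KeyError(f"CPI table has no entry for year(s) {bad}")
    return (cents * factor + 0.5).astype("int64")  # exact cents after adjustment


def summarize_costs(
    bundle: ClaimsBundle,
    members: pd.DataFrame,
    window: WindowSpec,
    scope: str = "all_cause",
    cpi: dict[int, float] | None = None,
    config: MfRelatedConfig = MfRelatedConfig(),
) -> CostSummary:
    """Combined plan + patient paid costs per member over ``window``,
    CPI-adjusted to 2018 USD, bucketed by setting plus pharmacy.

    The accounting identity holds at cent precision per patient:
    medical = office + outpatient + ed + inpatient + other, and
    total = medical + pharmacy.
    """
    cpi = cpi or load_cpi_table()
    med = bundle.medical_claims.copy()
    rx = bundle.pharmacy_claims.copy()
    if scope == "mf_related":
        med = med[_medical_mask_mf(med, config)]
        rx = rx[rx["agent"].isin(config.mf_agents)]
    elif scope != "all_cause":
        raise ValueError(f"unknown scope {scope!r}")
    med["adj_cents"] = _adjusted_cents(med, "service_date", cpi)
    rx["adj_cents"] = _adjusted_cents(rx, "fill_date", cpi)

    key = members[["patient_id", "index_date"]]
    mm = med.merge(key, on="patient_id", how="inner")
    mm = mm[_in_window_mask(mm, "service_date", window)]
    comp = mm["setting"].where(mm["setting"].isin(COST_COMPONENTS), "other")
    med_sums = (mm.assign(component=comp)
                .groupby(["patient_id", "component"], sort=False)["adj_cents"].sum()
                .unstack(fill_value=0))
    pp = rx.merge(key, on="patient_id", how="inner")
    pp = pp[_in_window_mask(pp, "fill_date", window)]
    rx_sums = pp.groupby("patient_id", sort=False)["adj_cents"].sum()

    per_patient = pd.DataFrame({"patient_id": members["patient_id"].values})
    for c in COST_COMPONENTS:
        col = med_sums[c] if c in med_sums.columns else pd.Series(dtype="int64")
        per_patient[c] = per_patient["patient_id"].map(col).fillna(0).astype("int64")
    per_patient["medical"] = per_patient[list(COST_COMPONENTS)].sum(axis=1)
    per_patient["pharmacy"] = (per_patient["patient_id"].map(rx_sums)
                               .fillna(0).astype("int64"))
    per_patient["total"] = per_patient["medical"] + per_patient["pharmacy"]

    out = []
    for comp in ("total", "medical", *COST_COMPONENTS, "pharmacy"):
        dollars = per_patient[comp] / 100.0 if len(per_patient) else pd.Series(dtype=float)
        out.append({
            "component": comp,
            "mean": float(dollars.mean()) if len(dollars) else np.nan,
            "sd": float(dollars.std(ddof=1)) if len(dollars) > 1 else np.nan,
        })
    return CostSummary(window.label, scope, len(members), pd.DataFrame(out), per_patient)


__all__ = [
    "COST_COMPONENTS",
    "CostSummary",
    "HCRU_CATEGORIES",
    "HcruSummary",
    "MfRelatedConfig",
    "POST6",
    "PRE6",
    "REFERENCE_YEAR",
    "WindowSpec",
    "adjust_cpi",
    "group_inpatient_admissions",
    "is_mf_related",
    "load_cpi_table",
    "summarize_costs",
    "summarize_hcru",
]
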