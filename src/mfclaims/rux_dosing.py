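"""Ruxolitinib (RUX) dose reconstruction from pharmacy fills.

A fill's daily dose is ``strength_mg × quantity / days_supply``, rounded
to the nearest milligram; fills dispensed on the same day are summed
(split-strength titration packs are one prescription). Over the 6-month
window anchored at the index RUX date the profile records:

* starting dose (dose on the index-date fill) and its duration,
* maximum daily dose and total covered days at that dose,
* dose modifications (changes between consecutive fill days, after
  rounding), overall and within the first 3 months,
* discontinuation — a gap of more than 45 days in days'-supply coverage
  after a run-out, provided the full gap is observable before the
  window end,
* therapy duration in months (covered span / 30.4375 days per month).

The maximum dose stratifies patients into the suboptimally dosed
(SUB, < 30 mg/day) and optimally dosed (OPT, ≥ 30 mg/day) cohorts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

DAYS_PER_MONTH = 30.4375
DOSE_BANDS = ("<15", "15-29", "30-40", ">40")
OPT_THRESHOLD_MG = 30.0


@dataclass(frozen=True)
class DosingConfig:
    window_days: int = 183          # [rux_index, rux_index + 182]
    gap_days: int = 45
    modification_window_days: int = 91  # first 3 months
    rux_agent: str = "ruxolitinib"


@dataclass
class RuxProfile:
    patient_id: str
    index_rux_date: pd.Timestamp
    starting_dose: float            # mg/day
    starting_dose_duration: int     # days
    max_dose: float                 # mg/day
    max_dose_duration: int          # days
    n_modifications: int
    modified_within_3mo: bool
    discontinued: bool
    therapy_duration_months: float

    @property
    def dose_band(self) -> str:
        return dose_band(self.max_dose)

    @property
    def cohort(self) -> str:
        return assign_cohort(self)


def daily_dose(fill: pd.Series | dict) -> float:
    """Daily dose of one fill in mg/day, rounded to the nearest 1 mg."""
    ds = int(fill["days_supply"])
    if ds <= 0:
        raise ValueError("days_supply must be positive")
    return float(math.floor(fill["strength_mg"] * fill["quantity"] / ds + 0.5))


def dose_band(max_dose: float) -> str:
    if max_dose < 15:
        return "<15"
    if max_dose < 30:
        return "15-29"
    if max_dose <= 40:
        return "30-40"
    return ">40"


def assign_cohort(profile: "RuxProfile") -> str:
    """SUB (suboptimal) iff max dose < 30 mg/day, else OPT."""
    return "SUB" if profile.max_dose < OPT_THRESHOLD_MG else "OPT"


def build_profile(
    fills: pd.DataFrame,
    index_rux_date,
    config: DosingConfig = DosingConfig(),
) -> RuxProfile:
    """Reconstruct one patient's RUX profile from fills in the 6-month
    post-index-RUX window. Requires a fill on the index date (the index
    is defined as the first fill)."""
    idx = pd.Timestamp(index_rux_date)
    win_end = idx + pd.Timedelta(days=config.window_days - 1)
    f = fills[(fills["agent"] == config.rux_agent)
              & (fills["fill_date"] >= idx) & (fills["fill_date"] <= win_end)]
    if not len(f):
        raise ValueError("no RUX fills in window; index RUX date requires one")

    idx_day = idx.toordinal()
    end_day = win_end.toordinal()

    # one entry per fill day: summed daily dose, max coverage length
    groups: dict[int, dict] = {}
    for _, row in f.iterrows():
        day = row["fill_date"].toordinal()
        g = groups.setdefault(day, {"dose": 0.0, "supply": 0})
        g["dose"] += daily_dose(row)
        g["supply"] = max(g["supply"], int(row["days_supply"]))
    days = sorted(groups)
    if days[0] != idx_day:
        raise ValueError("no fill on the index RUX date")
    doses = [groups[d]["dose"] for d in days]

    starting = doses[0]
    max_dose = max(doses)

    # coverage chain with <= gap_days bridging; run-out where a longer hole opens
    covered_end = days[0] + groups[days[0]]["supply"] - 1
    runout = None
    for d in days[1:]:
        if d > covered_end + config.gap_days:
            if runout is None:
                runout = covered_end
        covered_end = max(covered_end, d + groups[d]["supply"] - 1)
    last_covered = min(covered_end, end_day)
    if runout is None:
        runout = covered_end
    discontinued = runout + config.gap_days < end_day

    # starting-dose duration: until the day before the first different dose,
    # else until run-out / window end
    change_day = next((d for d, v in zip(days[1:], doses[1:]) if v != starting), None)
    if change_day is not None:
        starting_duration = change_day - idx_day
    else:
        starting_duration = min(runout, end_day) - idx_day + 1

    # covered days dispensed at the max dose, clipped to the window
    max_duration = sum(
        max(0, min(d + groups[d]["supply"] - 1, end_day) - d + 1)
        for d, v in zip(days, doses) if v == max_dose
    )

    n_mod = sum(1 for a, b in zip(doses, doses[1:]) if a != b)
    mod_3mo = any(
        b != a and d <= idx_day + config.modification_window_days - 1
        for a, b, d in zip(doses, doses[1:], days[1:])
    )

    months = (last_covered - idx_day + 1) / DAYS_PER_MONTH
    return RuxProfile(
        patient_id=str(f.iloc[0]["patient_id"]),
        index_rux_date=idx,
        starting_dose=starting,
        starting_dose_duration=int(starting_duration),
        max_dose=max_dose,
        max_dose_duration=int(max_duration),
        n_modifications=n_mod,
        modified_within_3mo=bool(mod_3mo),
        discontinued=bool(discontinued),
        therapy_duration_months=float(months),
    )


def profiles_to_frame(profiles: list[RuxProfile]) -> pd.DataFrame:
    rows = [{
        "patient_id": p.patient_id,
        "index_rux_date": p.index_rux_date,
        "starting_dose": p.starting_dose,
        "starting_dose_duration": p.starting_dose_duration,
        "max_dose": p.max_dose,
        "max_dose_duration": p.max_dose_duration,
        "dose_band": p.dose_band,
        "cohort": p.cohort,
        "n_modifications": p.n_modifications,
        "modified_within_3mo": p.modified_within_3mo,
        "discontinued": p.discontinued,
        "therapy_duration_months": p.therapy_duration_months,
    } for p in profiles]
    return pd.DataFrame(rows, columns=[
        "patient_id", "index_rux_date", "starting_dose",
        "starting_dose_duration", "max_dose", "max_dose_duration",
        "dose_band", "cohort", "n_modifications", "modified_within_3mo",
        "discontinued", "therapy_duration_months"])


@dataclass
class DosingSummary:
    n: int
    median_starting_dose: float
    mean_starting_dose_duration: float
    sd_starting_dose_duration: float
    median_max_dose: float
    mean_max_dose_duration: float
    sd_max_dose_duration: float
    pct_modified: float
    pct_modified_within_3mo: float
    band_table: pd.DataFrame        # dose_band, n, pct
    cohort_table: pd.DataFrame      # cohort, n, pct_discontinued, mean_duration_months


def summarize_dosing(profiles: list[RuxProfile] | pd.DataFrame) -> DosingSummary:
    """Dosing-pattern table: starting/max dose summaries, dose-band
    distribution, and per-cohort (SUB/OPT) discontinuation and mean
    therapy duration."""
    df = profiles if isinstance(profiles, pd.DataFrame) else profiles_to_frame(profiles)
    n = len(df)
    band = pd.DataFrame({
        "dose_band": DOSE_BANDS,
        "n": [int((df["dose_band"] == b).sum()) for b in DOSE_BANDS],
    })
    band["pct"] = 100.0 * band["n"] / n if n else np.nan
    cohort_rows = []
    for c in ("SUB", "OPT"):
        sub = df[df["cohort"] == c]
        cohort_rows.append({
            "cohort": c,
            "n": len(sub),
            "pct_discontinued": 100.0 * sub["discontinued"].mean() if len(sub) else np.nan,
            "mean_duration_months": float(sub["therapy_duration_months"].mean())
            if len(sub) else np.nan,
        })
    return DosingSummary(
        n=n,
        median_starting_dose=float(df["starting_dose"].median()) if n else np.nan,
        mean_starting_dose_duration=float(df["starting_dose_duration"].mean()) if n else np.nan,
        sd_starting_dose_duration=float(df["starting_dose_duration"].std(ddof=1)) if n > 1 else np.nan,
        median_max_dose=float(df["max_dose"].median()) if n else np.nan,
        mean_max_dose_duration=float(df["max_dose_duration"].mean()) if n else np.nan,
        sd_max_dose_duration=float(df["max_dose_duration"].std(ddof=1)) if n > 1 else np.nan,
        pct_modified=100.0 * (df["n_modifications"] > 0).mean() if n else np.nan,
        pct_modified_within_3mo=100.0 * df["modified_within_3mo"].mean() if n else np.nan,
        band_table=band,
        cohort_table=pd.DataFrame(cohort_rows),
    )


__all__ = [
    "DAYS_PER_MONTH",
    "DOSE_BANDS",
    "DosingConfig",
    "DosingSummary",
    "OPT_THRESHOLD_MG",
    "RuxProfile",
    "assign_cohort",
    "build_profile",
    "daily_dose",
    "dose_band",
    "profiles_to_frame",
    "summarize_dosing",
]
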