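"""Statistical comparisons, report tables, and the end-to-end pipeline.

Continuous variables are compared with a two-sided Welch
(unequal-variance) t-test and categorical variables with a Pearson
chi-square test without continuity correction, matching the study's
descriptive-comparison design; no multiple-testing adjustment is
applied. ``run_pipeline`` chains generation (optional) → selection →
comorbidity → LOT derivation → RUX dosing → HCRU/cost summaries →
report artifacts (CSV tables and bar-chart figures), deterministically
for a fixed seed.
"""

from __future__ import annotations

import logging
import os
import time
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from . import synthetic_claims
from .claims_model import ClaimsBundle
from .cohort_builder import (SelectionConfig, apply_primary_selection,
                             apply_subgroup_selection)
from .comorbidity import profile_cohort
from .hcru_cost import POST6, PRE6, summarize_costs, summarize_hcru
from .lot_engine import (LotConfig, derive_lots, extract_agent_events,
                         lots_to_frame, summarize_lots)
from .rux_dosing import build_profile, profiles_to_frame, summarize_dosing

log = logging.getLogger("mfclaims")


@dataclass
class ComparisonResult:
    variable: str
    group_labels: tuple[str, str]
    group_summaries: tuple
    test: str
    statistic: float
    p_value: float


def t_test(a, b, variable: str = "", labels: tuple[str, str] = ("a", "b")
           ) -> ComparisonResult:
    """Two-sided Welch unequal-variance t-test on two value groups."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("t_test requires n >= 2 in each group")
    if not (np.isfinite(a).all() and np.isfinite(b).all()):
        raise ValueError("t_test requires finite values")
    res = stats.ttest_ind(a, b, equal_var=False)
    return ComparisonResult(
        variable, labels,
        ((float(a.mean()), float(a.std(ddof=1))), (float(b.mean()), float(b.std(ddof=1)))),
        "t_test", float(res.statistic), float(res.pvalue))


def chi_square_test(table, variable: str = "", labels: tuple[str, str] = ("a", "b")
                    ) -> ComparisonResult:
    """Pearson chi-square on a 2×k contingency table, no continuity
    correction, df = k − 1."""
    obs = np.asarray(table, dtype=float)
    if (obs < 0).any():
        raise ValueError("counts must be non-negative")
    if (obs.sum(axis=0) == 0).any() or (obs.sum(axis=1) == 0).any():
        raise ValueError("chi-square requires positive margins")
    res = stats.chi2_contingency(obs, correction=False)
    ns = obs.sum(axis=1)
    return ComparisonResult(
        variable, labels,
        tuple((row.tolist(), float(n)) for row, n in zip(obs, ns)),
        "chi_square", float(res.statistic), float(res.pvalue))


# ---------------------------------------------------------------------------
# Pipeline
# ---------------------------------------------------------------------------


@dataclass
class PipelineResult:
    bundle: ClaimsBundle
    primary: object
    subgroup: object
    comorbidity: pd.DataFrame
    lots: pd.DataFrame
    lot_summary: object
    profiles: pd.DataFrame
    dosing_summary: object
    hcru: dict
    costs: dict
    truth: pd.DataFrame | None = None


def _follow_up_end(bundle: ClaimsBundle, patient_id: str,
                   cutoff: pd.Timestamp) -> pd.Timestamp:
    spans = bundle.enrollment[bundle.enrollment["patient_id"] == patient_id]
    end = spans["end_date"].max() if len(spans) else cutoff
    return min(end, cutoff)


def derive_cohort_lots(bundle: ClaimsBundle, members: pd.DataFrame,
                       sel: SelectionConfig = SelectionConfig(),
                       lot_cfg: LotConfig = LotConfig()) -> pd.DataFrame:
    """LOT table for every cohort member (long, ≤2 rows per patient)."""
    death_by = bundle.patients.set_index("patient_id")["death_date"]
    med_by = dict(tuple(bundle.medical_claims.groupby("patient_id", sort=False)))
    rx_by = dict(tuple(bundle.pharmacy_claims.groupby("patient_id", sort=False)))
    enr_by = dict(tuple(bundle.enrollment.groupby("patient_id", sort=False)))
    empty_med = bundle.medical_claims.iloc[0:0]
    empty_rx = bundle.pharmacy_claims.iloc[0:0]
    frames = []
    for _, r in members.iterrows():
        pid = r["patient_id"]
        mini = ClaimsBundle(bundle.patients.iloc[0:0], bundle.enrollment.iloc[0:0],
                            med_by.get(pid, empty_med), rx_by.get(pid, empty_rx))
        events = extract_agent_events(mini, pid, r["index_date"], lot_cfg)
        spans = enr_by.get(pid)
        fend = min(spans["end_date"].max() if spans is not None else sel.study_cutoff,
                   sel.study_cutoff)
        death = death_by.get(pid)
        lots = derive_lots(events, fend, death, lot_cfg)
        if lots:
            frames.append(lots_to_frame(lots))
    if not frames:
        return lots_to_frame([])
    return pd.concat(frames, ignore_index=True)


def build_rux_profiles(bundle: ClaimsBundle, subgroup_members: pd.DataFrame
                       ) -> pd.DataFrame:
    rx_by = dict(tuple(bundle.pharmacy_claims.groupby("patient_id", sort=False)))
    profiles = []
    for _, r in subgroup_members.iterrows():
        fills = rx_by.get(r["patient_id"])
        profiles.append(build_profile(fills, r["index_date"]))
    return profiles_to_frame(profiles)


def run_pipeline(
    params: "synthetic_claims.GeneratorParams | None" = None,
    bundle: ClaimsBundle | None = None,
    outdir: str | None = None,
    sel: SelectionConfig = SelectionConfig(),
    lot_cfg: LotConfig = LotConfig(),
    make_figures: bool = True,
) -> PipelineResult:
    """Run every stage end-to-end on a generated or supplied bundle.

    If ``outdir`` is given, report artifacts are written there (see
    :func:`build_reports`)."""
    t0 = time.time()
    truth = None
    if bundle is None:
        bundle, truth = synthetic_claims.generate_with_truth(params)
        log.info("generate: %d patients, %d medical, %d pharmacy claims (%.1fs)",
                 bundle.n_patients, len(bundle.medical_claims),
                 len(bundle.pharmacy_claims), time.time() - t0)

    primary = apply_primary_selection(bundle, sel)
    log.info("select: %d primary cohort members", len(primary.members))
    subgroup = apply_subgroup_selection(bundle, primary, sel)
    log.info("select: %d RUX subgroup members", len(subgroup.members))

    comorb = profile_cohort(bundle, primary.members,
                            lookback_days=sel.pre_index_days_primary)
    lots = derive_cohort_lots(bundle, primary.members, sel, lot_cfg)
    lot_summary = summarize_lots(lots)
    profiles = build_rux_profiles(bundle, subgroup.members)
    dosing_summary = summarize_dosing(profiles)

    hcru = {}
    costs = {}
    for window in (PRE6, POST6):
        for scope in ("all_cause", "mf_related"):
            hcru[(window.label, scope)] = summarize_hcru(
                bundle, primary.members, window, scope)
            costs[(window.label, scope)] = summarize_costs(
                bundle, primary.members, window, scope)

    result = PipelineResult(bundle, primary, subgroup, comorb, lots,
                            lot_summary, profiles, dosing_summary,
                            hcru, costs, truth)
    if outdir is not None:
        build_reports(result, outdir, make_figures=make_figures)
    log.info("pipeline complete (%.1fs)", time.time() - t0)
    return result


# ---------------------------------------------------------------------------
# Report artifacts
# ---------------------------------------------------------------------------


def table1(result: PipelineResult) -> pd.DataFrame:
    """Demographics and pre-index comorbidities, overall and SUB vs OPT
    with p-values (Welch t for age/CCI, chi-square for proportions)."""
    bundle = result.bundle
    members = result.primary.members
    pats = bundle.patients.set_index("patient_id")
    rows = []

    def add(variable, overall, sub=None, opt=None, p=np.nan):
        rows.append({"variable": variable, "overall": overall,
                     "sub_rux": sub, "opt_rux": opt, "p_value": p})

    if not len(members):
        return pd.DataFrame(rows, columns=["variable", "overall", "sub_rux",
                                           "opt_rux", "p_value"])
    age = members["index_date"].dt.year - members["patient_id"].map(pats["birth_year"])
    male = (members["patient_id"].map(pats["sex"]) == "male")
    prof = result.profiles
    sub_ids = set(prof.loc[prof["cohort"] == "SUB", "patient_id"])
    opt_ids = set(prof.loc[prof["cohort"] == "OPT", "patient_id"])
    in_sub = members["patient_id"].isin(sub_ids)
    in_opt = members["patient_id"].isin(opt_ids)

    def split_p_cont(series):
        a, b = series[in_sub], series[in_opt]
        if len(a) >= 2 and len(b) >= 2:
            return float(a.mean()), float(b.mean()), t_test(a, b).p_value
        return np.nan, np.nan, np.nan

    def split_p_cat(flags):
        a, b = flags[in_sub], flags[in_opt]
        if len(a) and len(b) and 0 < flags[in_sub | in_opt].mean() < 1:
            tab = [[a.sum(), len(a) - a.sum()], [b.sum(), len(b) - b.sum()]]
            return (100.0 * a.mean(), 100.0 * b.mean(),
                    chi_square_test(tab).p_value)
        return (100.0 * a.mean() if len(a) else np.nan,
                100.0 * b.mean() if len(b) else np.nan, np.nan)

    s, o, p = split_p_cont(age)
    add("age_mean", float(age.mean()), s, o, p)
    s, o, p = split_p_cat(male)
    add("male_pct", 100.0 * male.mean(), s, o, p)
    add("primary_mf_pct", 100.0 * (members["diagnosis_type"] == "primary_mf").mean())

    comorb = result.comorbidity.set_index("patient_id").reindex(members["patient_id"])
    cci = comorb["cci_score"].reset_index(drop=True)
    s, o, p = split_p_cont(cci)
    add("cci_mean", float(cci.mean()), s, o, p)
    add("cci_ge5_pct", 100.0 * comorb["cci_ge5"].mean())
    for cat in [c for c in comorb.columns if c not in ("cci_score", "cci_ge5")]:
        flags = comorb[cat].reset_index(drop=True).astype(bool)
        s, o, p = split_p_cat(flags)
        add(f"ahrq_{cat}_pct", 100.0 * flags.mean(), s, o, p)
    return pd.DataFrame(rows)


def build_reports(result: PipelineResult, outdir: str, make_figures: bool = True
                  ) -> dict[str, str]:
    """Write attrition, table1, table2 (LOT), dosing, HCRU and cost CSVs
    plus cost-component and discontinuation bar charts."""
    os.makedirs(outdir, exist_ok=True)
    paths = {}

    def save(name: str, df: pd.DataFrame):
        p = os.path.join(outdir, name)
        df.to_csv(p, index=False)
        paths[name] = p

    att = result.primary.attrition.copy()
    att["analysis"] = "primary"
    att2 = result.subgroup.attrition.copy()
    att2["analysis"] = "subgroup"
    save("attrition.csv", pd.concat([att, att2], ignore_index=True))
    save("table1.csv", table1(result))
    save("table2.csv", result.lot_summary.per_line)
    dosing = result.dosing_summary
    save("dosing_bands.csv", dosing.band_table)
    save("dosing_cohorts.csv", dosing.cohort_table)
    save("lots.csv", result.lots)
    save("rux_profiles.csv", result.profiles)

    hcru_rows, cost_rows = [], []
    for (window, scope), summ in result.hcru.items():
        t = summ.table.copy()
        t.insert(0, "scope", scope)
        t.insert(0, "window", window)
        hcru_rows.append(t)
    for (window, scope), summ in result.costs.items():
        t = summ.table.copy()
        t.insert(0, "scope", scope)
        t.insert(0, "window", window)
        cost_rows.append(t)
    save("hcru.csv", pd.concat(hcru_rows, ignore_index=True))
    save("costs.csv", pd.concat(cost_rows, ignore_index=True))

    if make_figures and len(result.primary.members):
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, axes = plt.subplots(1, 2, figsize=(10, 4))
        for ax, scope in zip(axes, ("all_cause", "mf_related")):
            comp = ("inpatient", "outpatient", "office", "ed", "other", "pharmacy")
            pre = result.costs[("pre6", scope)].table.set_index("component")["mean"]
            post = result.costs[("post6", scope)].table.set_index("component")["mean"]
            x = np.arange(len(comp))
            ax.bar(x - 0.2, [pre[c] for c in comp], width=0.4, label="pre-index")
            ax.bar(x + 0.2, [post[c] for c in comp], width=0.4, label="post-index")
            ax.set_xticks(x, comp, rotation=45, ha="right")
            ax.set_ylabel("mean cost per patient (2018 USD)")
            ax.set_title(scope.replace("_", "-"))
            ax.legend()
        fig.tight_layout()
        fig.savefig(os.path.join(outdir, "fig_costs.png"), dpi=120)
        plt.close(fig)
        paths["fig_costs.png"] = os.path.join(outdir, "fig_costs.png")

        ct = result.dosing_summary.cohort_table
        if len(ct) and ct["n"].sum() > 0:
            fig, axes = plt.subplots(1, 2, figsize=(8, 3.5))
            axes[0].bar(ct["cohort"], ct["mean_duration_months"], color=["#c44", "#48a"])
            axes[0].set_ylabel("mean RUX duration (months)")
            axes[1].bar(ct["cohort"], ct["pct_discontinued"], color=["#c44", "#48a"])
            axes[1].set_ylabel("discontinued (%)")
            fig.tight_layout()
            fig.savefig(os.path.join(outdir, "fig_rux.png"), dpi=120)
            plt.close(fig)
            paths["fig_rux.png"] = os.path.join(outdir, "fig_rux.png")
    return paths


__all__ = [
    "ComparisonResult",
    "PipelineResult",
    "build_reports",
    "build_rux_profiles",
    "chi_square_test",
    "derive_cohort_lots",
    "run_pipeline",
    "t_test",
    "table1",
]
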