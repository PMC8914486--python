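"""Synthetic administrative-claims generator for myelofibrosis cohorts.

Emits :class:`~mfclaims.claims_model.ClaimsBundle` objects with the
statistical structure the downstream analysis assumes — enrollment
windows compatible with the selection criteria, MF diagnosis claims
that create a valid index date, treated patients whose pharmacy/medical
claims realize a sampled regimen sequence, RUX fill trajectories whose
recomputed daily doses land in a sampled maximum-dose band, and
per-window lognormal cost totals allocated across claims — so every
pipeline stage is testable without proprietary data.

Default parameters are calibrated to the study's printed marginals:
age 70 (SD 12), 54% male, 24% primary MF, 60% treated, 46% of treated
with a second line, first-line regimen mix 39/4/31/10/16% (RUX
monotherapy / RUX combination / hydroxyurea / azacitidine-decitabine /
other), maximum-dose bands 14/25/56/6% (<15 / 15-29 / 30-40 /
>40 mg/day), discontinuation 29% (SUB) vs 20% (OPT), mean therapy
duration 4.9 vs 5.3 months, and post-index mean all-cause total cost
$48,966 ($24,216 pre-index).

Fill trajectories use 30-day supplies; the per-cohort fill-count
distribution for discontinuers is derived in closed form from the
target mean durations, so the configured duration and discontinuation
marginals are recovered by construction. A ground-truth sidecar table
records every sampled latent (regimen, dose band, discontinuation,
comorbidity flags, window cost totals) for recovery tests.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from .claims_model import ClaimsBundle, join_codes, normalize_code
from .rux_dosing import DAYS_PER_MONTH

ICD10_START = pd.Timestamp("2015-10-01")
STUDY_CUTOFF = pd.Timestamp("2018-06-30")
# index dates sampled so that even a late second-line RUX window closes
# before the study cut-off (see docs/methods.md)
INDEX_SAMPLING_START = pd.Timestamp("2013-01-01")
INDEX_SAMPLING_END = pd.Timestamp("2017-03-31")

POST_WINDOW_DAYS = 183

# (ICD-10, ICD-9) implant code per AHRQ category; chosen to hit exactly
# one packaged category prefix and no Charlson condition
AHRQ_IMPLANTS = {
    "anemia": ("D64.9", "285.9"),
    "hypertension": ("I10", "401.9"),
    "heart_disease": ("I25.10", "414.01"),
    "dyslipidemia": ("E78.5", "272.4"),
    "urinary_system_disease": ("N39.0", "599.0"),
    "other_gastrointestinal_disorders": ("K59.09", "564.00"),
    "other_hematologic_conditions": ("D69.6", "287.5"),
    "neoplasms_unspecified_uncertain": ("D48.9", "238.9"),
}

# Charlson condition implants (ICD-10, ICD-9), disjoint from the AHRQ
# prefixes so category prevalences stay independently calibrated
CHARLSON_IMPLANTS = {
    "diabetes_uncomplicated": ("E11.9", "250.00"),
    "chronic_pulmonary": ("J44.9", "496"),
    "pvd": ("I70.9", "443.9"),
    "dementia": ("G30.9", "290.0"),
    "hemiplegia": ("G81.9", "342.90"),
    "renal": ("Z99.2", "V45.11"),
    "malignancy": ("C34.90", "162.9"),
    "severe_liver": ("I85.0", "456.0"),
    "metastatic_tumor": ("C78.7", "197.7"),
}
# implant probabilities targeting a mean CCI near 2.1
CHARLSON_PROBS = {
    "diabetes_uncomplicated": 0.25, "chronic_pulmonary": 0.25, "pvd": 0.25,
    "dementia": 0.08, "hemiplegia": 0.05, "renal": 0.20, "malignancy": 0.25,
    "severe_liver": 0.05, "metastatic_tumor": 0.02,
}

GENERIC_DX = ("R53.83", "780.79")  # fatigue; unmapped by CCI/AHRQ
PREGNANCY_DX = ("Z33.1", "V22.2")
PRELAB_PROB = 0.6  # chance of diagnostic-only MF work-up labs pre-index
# share of post-index ambulatory claims carrying an MF code in any
# position; set so MF-related costs track the printed all-cause share
MF_AMBULATORY_DX_PROB = 0.75

BAND_DOSES = {
    "<15": ((5.0, 0.4), (10.0, 0.6)),
    "15-29": ((15.0, 0.3), (20.0, 0.4), (25.0, 0.3)),
    "30-40": ((30.0, 0.6), (35.0, 0.15), (40.0, 0.25)),
    ">40": ((45.0, 0.5), (50.0, 0.5)),
}

OTHER_1L_AGENTS = ("danazol", "thalidomide", "lenalidomide", "melphalan")
MED_ADMIN_JCODE = {"azacitidine": "J9025", "decitabine": "J0894"}


def _default_first_line_mix():
    return {"rux_monotherapy": 0.39, "rux_combination": 0.04,
            "hydroxyurea_monotherapy": 0.31, "aza_dec_monotherapy": 0.10,
            "other": 0.16}


def _default_band_mix():
    # exact band counts 68/123/276/28 of 495 (rounded: 14/25/56/6%)
    return {"<15": 68 / 495, "15-29": 123 / 495, "30-40": 276 / 495, ">40": 28 / 495}


def _default_cost_params():
    # lognormal mean/sd in dollars; pre totals target $24,216 and post
    # totals $48,966 (medical + pharmacy); sds are free parameters
    return {
        "pre": {"medical_mean": 18000.0, "medical_sd": 22000.0,
                "pharmacy_mean": 6216.0, "pharmacy_sd": 7000.0},
        "post": {"medical_mean": 29583.0, "medical_sd": 35000.0,
                 "pharmacy_mean": 19383.0, "pharmacy_sd": 20000.0},
    }


def _default_comorbidity_prevalences():
    return {"anemia": 0.71, "hypertension": 0.66, "heart_disease": 0.57,
            "dyslipidemia": 0.56, "urinary_system_disease": 0.52,
            "other_gastrointestinal_disorders": 0.51,
            "other_hematologic_conditions": 0.48,
            "neoplasms_unspecified_uncertain": 0.79}


def _default_hcru_rates():
    return {"office_mean": 3.0, "outpatient_mean": 2.5, "ed_prob": 0.20,
            "inpatient_prob_pre": 0.22, "inpatient_prob_post": 0.30}


def _default_region_mix():
    return {"Northeast": 0.17, "Midwest": 0.32, "South": 0.38,
            "West": 0.13, "Other": 0.0}


@dataclass
class GeneratorParams:
    n_patients: int = 2000
    seed: int = 0
    age_mean: float = 70.0
    age_sd: float = 12.0
    prop_male: float = 0.54
    prop_primary_mf: float = 0.24
    prop_treated: float = 0.60
    prop_second_lot_given_treated: float = 0.46
    first_line_mix: dict = field(default_factory=_default_first_line_mix)
    rux_max_dose_band_mix: dict = field(default_factory=_default_band_mix)
    disc_prob_sub: float = 0.29
    disc_prob_opt: float = 0.20
    duration_mean_sub: float = 4.9      # months
    duration_mean_opt: float = 5.3
    cost_params: dict = field(default_factory=_default_cost_params)
    comorbidity_prevalences: dict = field(default_factory=_default_comorbidity_prevalences)
    enrollment_dropout_hazard: float = 0.005    # per month post-index
    charlson_probs: dict = field(default_factory=lambda: dict(CHARLSON_PROBS))
    region_mix: dict = field(default_factory=_default_region_mix)
    hcru_rates: dict = field(default_factory=_default_hcru_rates)
    pregnancy_prob: float = 0.01
    trial_prob: float = 0.005
    death_prob: float = 0.03            # per treated (non-RUX-1L) patient
    p_dose_modification: float = 0.28
    rux_days_supply: int = 30

    def validate(self) -> None:
        if self.n_patients < 1:
            raise ValueError("n_patients must be >= 1")
        probs = {
            "prop_male": self.prop_male, "prop_primary_mf": self.prop_primary_mf,
            "prop_treated": self.prop_treated,
            "prop_second_lot_given_treated": self.prop_second_lot_given_treated,
            "disc_prob_sub": self.disc_prob_sub, "disc_prob_opt": self.disc_prob_opt,
            "enrollment_dropout_hazard": self.enrollment_dropout_hazard,
            "pregnancy_prob": self.pregnancy_prob, "trial_prob": self.trial_prob,
            "death_prob": self.death_prob,
            "p_dose_modification": self.p_dose_modification,
        }
        probs.update({f"comorbidity_prevalences[{k}]": v
                      for k, v in self.comorbidity_prevalences.items()})
        probs.update({f"charlson_probs[{k}]": v for k, v in self.charlson_probs.items()})
        for name, p in probs.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must be a probability in [0, 1], got {p}")
        for name, mix in (("first_line_mix", self.first_line_mix),
                          ("rux_max_dose_band_mix", self.rux_max_dose_band_mix),
                          ("region_mix", self.region_mix)):
            if abs(sum(mix.values()) - 1.0) > 1e-9:
                raise ValueError(f"{name} probabilities must sum to 1")
            if any(v < 0 for v in mix.values()):
                raise ValueError(f"{name} has a negative probability")


def default_params() -> GeneratorParams:
    """The study-calibrated defaults (see module docstring)."""
    return GeneratorParams()


def params_from_yaml(path) -> GeneratorParams:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    base = dataclasses.asdict(GeneratorParams())
    unknown = set(raw) - set(base)
    if unknown:
        raise ValueError(f"unknown generator parameters: {sorted(unknown)}")
    base.update(raw)
    p = GeneratorParams(**base)
    p.validate()
    return p


def params_to_yaml(params: GeneratorParams, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(dataclasses.asdict(params), fh, sort_keys=False)


# ---------------------------------------------------------------------------
# Internal helpers
# ---------------------------------------------------------------------------


def _lognormal(rng, mean: float, sd: float) -> float:
    """Lognormal draw parameterized by target mean/sd (moment matching)."""
    if mean <= 0:
        return 0.0
    sigma2 = np.log(1.0 + (sd / mean) ** 2)
    mu = np.log(mean) - sigma2 / 2.0
    return float(rng.lognormal(mu, np.sqrt(sigma2)))


def _pick(rng, mix: dict) -> str:
    keys = list(mix)
    return keys[rng.choice(len(keys), p=np.array([mix[k] for k in keys], dtype=float)
                           / sum(mix.values()))]


def _dx_for(pair: tuple[str, str], date: pd.Timestamp) -> tuple[str, str]:
    """(code, system) appropriate for the service date."""
    if date >= ICD10_START:
        return normalize_code(pair[0]), "ICD10"
    return normalize_code(pair[1]), "ICD9"


def _mf_dx(primary: bool, date: pd.Timestamp) -> tuple[str, str]:
    if primary:
        return _dx_for(("D47.4", "238.76"), date)
    return _dx_for(("D75.81", "289.83"), date)


def _disc_fill_p(duration_mean_months: float, disc_prob: float) -> float:
    """Success probability for the 1 + Binomial(3, p) fill count of
    discontinuers, solved so the overall mean therapy duration matches."""
    full = POST_WINDOW_DAYS / DAYS_PER_MONTH
    if disc_prob <= 0:
        return 0.0
    x = (duration_mean_months - (1.0 - disc_prob) * full) / disc_prob
    k_mean = x * DAYS_PER_MONTH / 30.0
    return float(min(max((k_mean - 1.0) / 3.0, 0.0), 1.0))


class _Emitter:
    """Accumulates claim rows with deterministic ids."""

    def __init__(self):
        self.patients: list[dict] = []
        self.enrollment: list[dict] = []
        self.medical: list[dict] = []
        self.pharmacy: list[dict] = []

    def med(self, pid, date, dxs, setting, diagnostic_only=False,
            procs=(), end_date=None):
        self.medical.append({
            "claim_id": f"M{len(self.medical) + 1:07d}",
            "patient_id": pid,
            "service_date": date,
            "end_date": end_date if end_date is not None else date,
            "dx_codes": join_codes(c for c, _ in dxs),
            "dx_systems": join_codes(s for _, s in dxs),
            "procedure_codes": join_codes(procs),
            "setting": setting,
            "diagnostic_only": diagnostic_only,
            "plan_paid_cents": 0,
            "patient_paid_cents": 0,
        })
        return self.medical[-1]

    def rx(self, pid, date, agent, strength, quantity, days_supply):
        self.pharmacy.append({
            "claim_id": f"P{len(self.pharmacy) + 1:07d}",
            "patient_id": pid,
            "fill_date": date,
            "agent": agent,
            "strength_mg": float(strength),
            "quantity": float(quantity),
            "days_supply": int(days_supply),
            "plan_paid_cents": 0,
            "patient_paid_cents": 0,
        })
        return self.pharmacy[-1]


def _rux_fill_fields(dose: float, days_supply: int) -> tuple[float, float]:
    """(strength, quantity) realizing ``dose`` mg/day from 5-mg units."""
    return 5.0, dose / 5.0 * days_supply


# ---------------------------------------------------------------------------
# Generation
# ---------------------------------------------------------------------------


def generate(params: GeneratorParams | None = None) -> ClaimsBundle:
    """Generate a claims bundle; deterministic for a fixed seed."""
    bundle, _ = generate_with_truth(params)
    return bundle


def generate_with_truth(params: GeneratorParams | None = None
                        ) -> tuple[ClaimsBundle, pd.DataFrame]:
    """Generate a bundle plus the ground-truth sidecar table (one row per
    patient with every sampled latent)."""
    params = params or default_params()
    params.validate()
    rng = np.random.default_rng(params.seed)
    em = _Emitter()
    truth_rows: list[dict] = []

    idx_lo = INDEX_SAMPLING_START.toordinal()
    idx_hi = INDEX_SAMPLING_END.toordinal()
    cutoff = STUDY_CUTOFF

    for i in range(params.n_patients):
        pid = f"PT{i + 1:06d}"
        med_start, rx_start = len(em.medical), len(em.pharmacy)
        index = pd.Timestamp.fromordinal(int(rng.integers(idx_lo, idx_hi + 1)))
        age = int(np.clip(round(rng.normal(params.age_mean, params.age_sd)), 18, 95))
        sex = "male" if rng.random() < params.prop_male else "female"
        region = _pick(rng, params.region_mix) if sum(params.region_mix.values()) else "Other"
        insurance = ("medicare_advantage"
                     if rng.random() < (0.75 if age >= 65 else 0.05) else "commercial")
        primary_mf = rng.random() < params.prop_primary_mf

        # --- latent treatment path -------------------------------------
        treated = rng.random() < params.prop_treated
        lot1_cat = _pick(rng, params.first_line_mix) if treated else None
        has_2l = treated and rng.random() < params.prop_second_lot_given_treated
        rux_in_1l = lot1_cat in ("rux_monotherapy", "rux_combination")

        death_date = None
        end_mode = None
        if treated and not rux_in_1l and not has_2l:
            end_mode = _pick(rng, {"discontinue": 0.40, "censor": 0.48,
                                   "transplant": 0.06, "death": 0.06})
            if end_mode == "death":
                death_date = index + pd.Timedelta(days=int(rng.integers(190, 401)))
        elif treated and rux_in_1l and not has_2l:
            end_mode = "rux_path"

        # --- enrollment -------------------------------------------------
        enroll_start = index - pd.Timedelta(days=420 + int(rng.integers(0, 181)))
        enroll_end = index + pd.Timedelta(days=540)
        dropped_out = False
        if params.enrollment_dropout_hazard > 0:
            months = int(rng.geometric(params.enrollment_dropout_hazard))
            if months * 30 < 540:
                enroll_end = index + pd.Timedelta(days=months * 30)
                dropped_out = True
        if death_date is not None:
            enroll_end = min(enroll_end, death_date)
        claims_end = min(enroll_end, cutoff)
        follow_end = claims_end

        spans = [(enroll_start, enroll_end)]
        if rng.random() < 0.2:
            split = index - pd.Timedelta(days=int(rng.integers(100, 301)))
            if enroll_start < split < enroll_end:
                spans = [(enroll_start, split), (split + pd.Timedelta(days=1), enroll_end)]
        for a, b in spans:
            em.enrollment.append({"patient_id": pid, "start_date": a, "end_date": b,
                                  "medical_benefit": True, "pharmacy_benefit": True})
        em.patients.append({"patient_id": pid, "birth_year": index.year - age,
                            "sex": sex, "region": region, "insurance": insurance,
                            "death_date": death_date if death_date is not None else pd.NaT})

        def emit_med(date, dxs, setting, **kw):
            if enroll_start <= date <= claims_end:
                return em.med(pid, date, dxs, setting, **kw)
            return None

        def emit_rx(date, agent, strength, quantity, ds):
            if enroll_start <= date <= claims_end:
                return em.rx(pid, date, agent, strength, quantity, ds)
            return None

        # --- MF diagnosis claims ----------------------------------------
        d2 = index + pd.Timedelta(days=int(rng.integers(30, 91)))
        emit_med(index, [_mf_dx(primary_mf, index)], "office")
        emit_med(d2, [_mf_dx(primary_mf, d2)], "office")
        if rng.random() < 0.3:  # diagnostic-only lab claim, ignored for the index
            dl = index + pd.Timedelta(days=int(rng.integers(5, 61)))
            emit_med(dl, [_mf_dx(primary_mf, dl)], "outpatient", diagnostic_only=True)
        # pre-index MF work-up labs: diagnostic-only, so they carry MF codes
        # without disturbing the index definition
        has_prelab = rng.random() < PRELAB_PROB
        if has_prelab:
            for _ in range(1 + int(rng.integers(0, 2))):
                dl = index - pd.Timedelta(days=int(rng.integers(10, 171)))
                emit_med(dl, [_mf_dx(primary_mf, dl)], "outpatient", diagnostic_only=True)

        # --- pre-index comorbidity claims -------------------------------
        # the MF work-up labs themselves flag one AHRQ category (primary MF
        # codes sit in the uncertain-neoplasm range, secondary in the
        # hematologic range); the sampled prevalence is deflated so each
        # category's marginal stays at the configured value
        mf_implied_cat = ("neoplasms_unspecified_uncertain" if primary_mf
                          else "other_hematologic_conditions")
        q_by_cat = {
            "neoplasms_unspecified_uncertain": PRELAB_PROB * params.prop_primary_mf,
            "other_hematologic_conditions": PRELAB_PROB * (1 - params.prop_primary_mf),
        }
        ahrq_flags = {}
        for cat, prev in params.comorbidity_prevalences.items():
            q = q_by_cat.get(cat, 0.0)
            p_adj = max((prev - q) / (1.0 - q), 0.0) if q < 1.0 else 0.0
            sampled = rng.random() < p_adj
            ahrq_flags[cat] = sampled or (has_prelab and cat == mf_implied_cat)
            if sampled:
                d = index - pd.Timedelta(days=int(rng.integers(10, 351)))
                emit_med(d, [_dx_for(AHRQ_IMPLANTS[cat], d)], "office")
        charlson_true = {}
        for cond, prob in params.charlson_probs.items():
            hit = rng.random() < prob
            charlson_true[cond] = hit
            if hit:
                d = index - pd.Timedelta(days=int(rng.integers(10, 351)))
                emit_med(d, [_dx_for(CHARLSON_IMPLANTS[cond], d)], "office")

        # --- pregnancy / trial sentinels --------------------------------
        pregnancy = sex == "female" and rng.random() < params.pregnancy_prob
        if pregnancy:
            d = index + pd.Timedelta(days=int(rng.integers(-180, 181)))
            emit_med(d, [_dx_for(PREGNANCY_DX, d)], "office")
        trial = rng.random() < params.trial_prob
        if trial:
            d = index + pd.Timedelta(days=int(rng.integers(-180, 181)))
            emit_med(d, [_dx_for(GENERIC_DX, d)], "office", procs=("S9988",))

        # --- background utilization -------------------------------------
        hr = params.hcru_rates
        inpatient_truth = {}
        for wname, lo, hi in (("pre", -183, -1), ("post", 0, 182)):
            n_office = 1 + int(rng.poisson(hr["office_mean"]))
            n_outpt = int(rng.poisson(hr["outpatient_mean"]))
            n_ed = 1 if rng.random() < hr["ed_prob"] else 0
            for _ in range(n_office):
                d = index + pd.Timedelta(days=int(rng.integers(lo, hi + 1)))
                dxs = [_dx_for(GENERIC_DX, d)]
                if wname == "post" and rng.random() < MF_AMBULATORY_DX_PROB:
                    dxs.append(_mf_dx(primary_mf, d))
                emit_med(d, dxs, "office")
            for _ in range(n_outpt):
                d = index + pd.Timedelta(days=int(rng.integers(lo, hi + 1)))
                dxs = [_dx_for(GENERIC_DX, d)]
                if wname == "post" and rng.random() < MF_AMBULATORY_DX_PROB:
                    dxs.append(_mf_dx(primary_mf, d))
                emit_med(d, dxs, "outpatient",
                         diagnostic_only=bool(rng.random() < 0.2))
            for _ in range(n_ed):
                d = index + pd.Timedelta(days=int(rng.integers(lo, hi + 1)))
                emit_med(d, [_dx_for(GENERIC_DX, d)], "ed")
            p_inp = hr["inpatient_prob_pre"] if wname == "pre" else hr["inpatient_prob_post"]
            has_inp = rng.random() < p_inp
            inpatient_truth[wname] = has_inp
            if has_inp:
                admit = index + pd.Timedelta(days=int(rng.integers(lo + 20, hi - 8)))
                stay = int(rng.integers(2, 8))
                discharge = admit + pd.Timedelta(days=stay)
                # MF codes only on/after the index claim: the index is the
                # first non-diagnostic MF claim, so none may precede it
                dxs = [_dx_for(GENERIC_DX, admit)]
                if wname == "post":
                    dxs.append(_mf_dx(primary_mf, admit))
                if rng.random() < 0.5:  # split stay into two abutting claims
                    mid = admit + pd.Timedelta(days=stay // 2)
                    emit_med(admit, dxs, "inpatient", end_date=mid)
                    emit_med(mid + pd.Timedelta(days=1), dxs, "inpatient",
                             end_date=discharge)
                else:
                    emit_med(admit, dxs, "inpatient", end_date=discharge)
            # background (non-MF-agent) pharmacy fills
            for _ in range(2 + int(rng.poisson(1.0))):
                d = index + pd.Timedelta(days=int(rng.integers(lo, hi + 1)))
                emit_rx(d, "atorvastatin", 20.0, 30.0, 30)

        # --- treatment claims -------------------------------------------
        rux_truth = {"rux_any": False, "rux_band": None, "rux_disc": None,
                     "rux_covered_days": None, "rux_start": pd.NaT}

        def emit_rux_course(start: pd.Timestamp) -> pd.Timestamp:
            """RUX fills from ``start``; returns last covered day.

            Samples band/dose/discontinuation per the SUB/OPT marginals and
            records them in ``rux_truth``."""
            band = _pick(rng, params.rux_max_dose_band_mix)
            doses, weights = zip(*BAND_DOSES[band])
            max_dose = float(doses[int(rng.choice(len(doses), p=weights))])
            sub = max_dose < 30.0
            disc_p = params.disc_prob_sub if sub else params.disc_prob_opt
            disc = rng.random() < disc_p
            ds = params.rux_days_supply
            if disc:
                p_k = _disc_fill_p(
                    params.duration_mean_sub if sub else params.duration_mean_opt,
                    disc_p)
                n_fills = 1 + int(rng.binomial(3, p_k))
                fill_days = [start + pd.Timedelta(days=ds * j) for j in range(n_fills)]
            else:
                fill_days = []
                d = start
                while d <= follow_end:
                    fill_days.append(d)
                    d += pd.Timedelta(days=ds)
                if not fill_days:   # start past follow-up (early disenrollment)
                    fill_days = [start]
            # dose trajectory; modification only when >= 2 fills and dose >= 10
            dose_seq = [max_dose] * len(fill_days)
            if (len(fill_days) >= 2 and max_dose >= 10.0
                    and rng.random() < params.p_dose_modification):
                step = 5.0 if max_dose <= 15.0 else 10.0
                if rng.random() < 0.5:
                    dose_seq[0] = max_dose - step          # up-titration
                else:
                    j = 2 if len(fill_days) >= 3 else 1    # later reduction
                    dose_seq[j:] = [max_dose - step] * (len(dose_seq) - j)
            for d, dose in zip(fill_days, dose_seq):
                strength, qty = _rux_fill_fields(dose, ds)
                emit_rx(d, "ruxolitinib", strength, qty, ds)
            covered = (fill_days[-1] - start).days + ds
            rux_truth.update(rux_any=True, rux_band=band, rux_disc=disc,
                             rux_covered_days=covered, rux_start=start)
            return fill_days[-1] + pd.Timedelta(days=ds - 1)

        def emit_agent_course(agent: str, start: pd.Timestamp,
                              n_units: int | None) -> pd.Timestamp:
            """Non-RUX course; ``n_units=None`` continues to follow-up end.
            Returns the last covered day."""
            if agent in MED_ADMIN_JCODE:
                cycle = 28
                d, k, last = start, 0, start
                while (n_units is None and d <= follow_end) or (n_units is not None and k < n_units):
                    if d > follow_end:
                        break
                    emit_med(d, [_dx_for(GENERIC_DX, d), _mf_dx(primary_mf, d)],
                             "outpatient", procs=(MED_ADMIN_JCODE[agent],))
                    last, k = d, k + 1
                    d += pd.Timedelta(days=cycle)
                return last + pd.Timedelta(days=cycle - 1)
            ds = 30
            d, k, last = start, 0, start
            while (n_units is None and d <= follow_end) or (n_units is not None and k < n_units):
                if d > follow_end:
                    break
                emit_rx(d, agent, 500.0, 30.0, ds)
                last, k = d, k + 1
                d += pd.Timedelta(days=ds)
            return last + pd.Timedelta(days=ds - 1)

        def sample_2l_agent(exclude: set[str]) -> str:
            pool = ["hydroxyurea", "azacitidine", "lenalidomide", "melphalan", "danazol"]
            pool = [a for a in pool if a not in exclude]
            return pool[int(rng.integers(0, len(pool)))]

        transplant = False
        if treated:
            s1 = index + pd.Timedelta(days=int(rng.integers(0, 31)))
            if rux_in_1l:
                runout = emit_rux_course(s1)
                if lot1_cat == "rux_combination":
                    partner_units = max(1, min(4, (runout - s1).days // 30 + 1)) \
                        if rux_truth["rux_disc"] else None
                    emit_agent_course("hydroxyurea",
                                      s1 + pd.Timedelta(days=int(rng.integers(0, 26))),
                                      partner_units)
                if has_2l:
                    agent2 = sample_2l_agent({"ruxolitinib", "hydroxyurea"}
                                             if lot1_cat == "rux_combination"
                                             else {"ruxolitinib"})
                    if rux_truth["rux_disc"]:
                        s2 = runout + pd.Timedelta(days=46 + int(rng.integers(0, 61)))
                    else:
                        s2 = s1 + pd.Timedelta(days=int(rng.integers(60, 121)))
                    s2 = max(s2, s1 + pd.Timedelta(days=30))
                    n2 = (1 + int(rng.binomial(4, 0.5))) if rng.random() < 0.6 else None
                    emit_agent_course(agent2, s2, n2)
            else:
                agent1 = {"hydroxyurea_monotherapy": "hydroxyurea",
                          "aza_dec_monotherapy":
                              ("azacitidine" if rng.random() < 0.5 else "decitabine"),
                          "other": OTHER_1L_AGENTS[int(rng.integers(0, len(OTHER_1L_AGENTS)))],
                          }[lot1_cat]
                if has_2l:
                    k1 = 1 + int(rng.binomial(3, 0.45))
                    runout = emit_agent_course(agent1, s1, k1)
                    if rng.random() < 0.35:  # immediate switch
                        s2 = runout + pd.Timedelta(days=1)
                    else:                    # discontinuation, later restart
                        s2 = runout + pd.Timedelta(days=46 + int(rng.integers(0, 61)))
                    s2 = max(s2, s1 + pd.Timedelta(days=30))
                    cat2 = _pick(rng, params.first_line_mix)
                    if cat2 in ("rux_monotherapy", "rux_combination"):
                        emit_rux_course(s2)
                        if cat2 == "rux_combination":
                            partner = sample_2l_agent({agent1, "ruxolitinib"})
                            emit_agent_course(
                                partner, s2 + pd.Timedelta(days=int(rng.integers(0, 26))),
                                1 + int(rng.binomial(3, 0.5)))
                    else:
                        agent2 = sample_2l_agent({agent1, "ruxolitinib"})
                        n2 = (1 + int(rng.binomial(4, 0.5))) if rng.random() < 0.6 else None
                        emit_agent_course(agent2, s2, n2)
                elif end_mode == "discontinue":
                    emit_agent_course(agent1, s1, 1 + int(rng.binomial(3, 0.45)))
                elif end_mode == "censor":
                    emit_agent_course(agent1, s1, None)
                elif end_mode == "transplant":
                    t_day = s1 + pd.Timedelta(days=int(rng.integers(10, 81)))
                    k1 = max(1, (t_day - s1).days // 30 + 1)
                    emit_agent_course(agent1, s1, k1)
                    proc = "38240" if rng.random() < 0.5 else "38100"
                    emit_med(t_day, [_dx_for(GENERIC_DX, t_day), _mf_dx(primary_mf, t_day)],
                             "inpatient", procs=(proc,),
                             end_date=t_day + pd.Timedelta(days=5))
                    transplant = True
                elif end_mode == "death":
                    n_units = max(1, (death_date - s1).days // 30)
                    emit_agent_course(agent1, s1, n_units)

        # --- per-window cost allocation ---------------------------------
        my_med = em.medical[med_start:]
        my_rx = em.pharmacy[rx_start:]
        lot_agents = set(MED_ADMIN_JCODE) | {"ruxolitinib", "hydroxyurea",
                                             "melphalan", "danazol",
                                             "thalidomide", "lenalidomide"}
        cost_truth = {}
        for wname, lo, hi in (("pre", -183, -1), ("post", 0, 182)):
            a = index + pd.Timedelta(days=lo)
            b = index + pd.Timedelta(days=hi)
            cp = params.cost_params[wname]
            med_in = [c for c in my_med if a <= c["service_date"] <= b]
            rx_in = [c for c in my_rx if a <= c["fill_date"] <= b]
            med_total = _lognormal(rng, cp["medical_mean"], cp["medical_sd"]) if med_in else 0.0
            rx_total = _lognormal(rng, cp["pharmacy_mean"], cp["pharmacy_sd"]) if rx_in else 0.0
            cost_truth[f"medical_cost_{wname}"] = med_total if med_in else 0.0
            cost_truth[f"pharmacy_cost_{wname}"] = rx_total if rx_in else 0.0
            _allocate(med_in, med_total,
                      lambda c: {"inpatient": 12.0, "ed": 2.0,
                                 "outpatient": 1.5}.get(c["setting"], 1.0),
                      "service_date")
            _allocate(rx_in, rx_total,
                      lambda c: 8.0 if c["agent"] in lot_agents else 1.0,
                      "fill_date")
        # claims outside the two analysis windows get schedule costs
        for c in my_med:
            if c["plan_paid_cents"] == 0 and c["patient_paid_cents"] == 0:
                base = {"office": 15000, "outpatient": 40000, "ed": 80000,
                        "inpatient": 1500000, "other": 20000}[c["setting"]]
                _set_cost(c, base, c["service_date"])
        for c in my_rx:
            if c["plan_paid_cents"] == 0 and c["patient_paid_cents"] == 0:
                base = 1200000 if c["agent"] in lot_agents else 5000
                _set_cost(c, base, c["fill_date"])

        truth_rows.append({
            "patient_id": pid, "index_mf_date": index, "age": age, "sex": sex,
            "primary_mf": primary_mf, "treated": treated,
            "lot1_category": lot1_cat, "has_2l": has_2l,
            "end_mode": end_mode, "transplant": transplant,
            "death_date": death_date if death_date is not None else pd.NaT,
            "dropped_out": dropped_out, "pregnancy": pregnancy, "trial": trial,
            **{f"ahrq_{k}": v for k, v in ahrq_flags.items()},
            **{f"charlson_{k}": v for k, v in charlson_true.items()},
            "inpatient_pre": inpatient_truth["pre"],
            "inpatient_post": inpatient_truth["post"],
            **cost_truth,
            **rux_truth,
        })

    bundle = ClaimsBundle(
        patients=pd.DataFrame(em.patients),
        enrollment=pd.DataFrame(em.enrollment),
        medical_claims=pd.DataFrame(em.medical),
        pharmacy_claims=pd.DataFrame(em.pharmacy),
    )
    for col in ("service_date", "end_date"):
        bundle.medical_claims[col] = pd.to_datetime(bundle.medical_claims[col])
    bundle.pharmacy_claims["fill_date"] = pd.to_datetime(bundle.pharmacy_claims["fill_date"])
    bundle.patients["death_date"] = pd.to_datetime(bundle.patients["death_date"])
    for col in ("start_date", "end_date"):
        bundle.enrollment[col] = pd.to_datetime(bundle.enrollment[col])
    return bundle, pd.DataFrame(truth_rows)


# CPI deflation note: drawn dollar totals are 2018 dollars; stored claim
# costs are nominal-year cents so the CPI adjustment at analysis time
# recovers the drawn values (see hcru_cost).
from .hcru_cost import REFERENCE_YEAR, load_cpi_table  # noqa: E402

_CPI = load_cpi_table()


def _nominal_cents(dollars_2018: float, date: pd.Timestamp) -> int:
    year = min(max(int(date.year), min(_CPI)), max(_CPI))
    return int(round(dollars_2018 * 100.0 * _CPI[year] / _CPI[REFERENCE_YEAR]))


def _set_cost(claim: dict, cents_2018: int, date: pd.Timestamp) -> None:
    total = _nominal_cents(cents_2018 / 100.0, date)
    patient = total // 10
    claim["plan_paid_cents"] = total - patient
    claim["patient_paid_cents"] = patient


def _allocate(claims: list[dict], total_dollars: float, weight_fn, date_key: str) -> None:
    """Split a window total (2018 dollars) across claims by weight, in
    exact cents, then deflate each share to its nominal year."""
    if not claims or total_dollars <= 0:
        return
    weights = np.array([weight_fn(c) for c in claims], dtype=float)
    shares = weights / weights.sum() * round(total_dollars * 100.0)
    cents = np.floor(shares).astype(int)
    remainder = int(round(total_dollars * 100.0)) - int(cents.sum())
    for j in range(remainder):
        cents[j % len(cents)] += 1
    for c, amt in zip(claims, cents):
        _set_cost(c, int(amt), c[date_key])


# ---------------------------------------------------------------------------
# Hand-specified single-patient scenarios
# ---------------------------------------------------------------------------

TOY_SCENARIOS = ("switch", "discontinue", "censor", "transplant",
                 "dose_escalation", "dose_reduction", "sub_opt_boundary")

_TOY_INDEX = pd.Timestamp("2016-01-04")


def generate_toy_patient(scenario: str) -> ClaimsBundle:
    """A 1-patient bundle with hand-specified dates reproducing one named
    treatment pathway (day 0 = the index MF date, 2016-01-04)."""
    if scenario not in TOY_SCENARIOS:
        raise ValueError(f"unknown scenario {scenario!r}; choose from {TOY_SCENARIOS}")
    em = _Emitter()
    pid = "TOY001"
    index = _TOY_INDEX

    def day(n: int) -> pd.Timestamp:
        return index + pd.Timedelta(days=n)

    enroll_end = day(200) if scenario == "censor" else day(540)
    em.patients.append({"patient_id": pid, "birth_year": 1950, "sex": "female",
                        "region": "Midwest", "insurance": "medicare_advantage",
                        "death_date": pd.NaT})
    em.enrollment.append({"patient_id": pid, "start_date": index - pd.Timedelta(days=400),
                          "end_date": enroll_end,
                          "medical_benefit": True, "pharmacy_benefit": True})
    for d in (day(0), day(40)):
        c = em.med(pid, d, [_mf_dx(True, d)], "office")
        _set_cost(c, 15000, d)

    def rux(d, dose, ds=30):
        strength, qty = _rux_fill_fields(dose, ds)
        c = em.rx(pid, d, "ruxolitinib", strength, qty, ds)
        _set_cost(c, 1200000, d)

    def hu(d, ds=30):
        c = em.rx(pid, d, "hydroxyurea", 500.0, 60.0, ds)
        _set_cost(c, 8000, d)

    if scenario == "switch":
        for d in (0, 30, 60):
            hu(day(d))
        hu(day(90), ds=10)          # coverage through day 99
        rux(day(100), 40.0)
    elif scenario == "discontinue":
        for d in (0, 30, 60):
            hu(day(d))              # coverage through day 89, then nothing
    elif scenario == "censor":
        for d in range(0, 181, 30):
            rux(day(d), 30.0)       # ongoing at follow-up end (day 200)
    elif scenario == "transplant":
        rux(day(0), 40.0)
        c = em.med(pid, day(10), [_mf_dx(True, day(10))], "inpatient",
                   procs=("38240",), end_date=day(15))
        _set_cost(c, 1500000, day(10))
    elif scenario == "dose_escalation":
        rux(day(0), 10.0)
        rux(day(30), 10.0)
        for d in range(60, 181, 30):
            rux(day(d), 20.0)
    elif scenario == "dose_reduction":
        rux(day(0), 40.0)
        rux(day(30), 40.0)
        for d in range(60, 181, 30):
            rux(day(d), 20.0)
    elif scenario == "sub_opt_boundary":
        for d in range(0, 181, 30):
            rux(day(d), 30.0)       # exactly 30 mg/day -> OPT

    bundle = ClaimsBundle(
        patients=pd.DataFrame(em.patients),
        enrollment=pd.DataFrame(em.enrollment),
        medical_claims=pd.DataFrame(em.medical),
        pharmacy_claims=pd.DataFrame(em.pharmacy),
    )
    return bundle


__all__ = [
    "AHRQ_IMPLANTS",
    "BAND_DOSES",
    "CHARLSON_IMPLANTS",
    "GeneratorParams",
    "INDEX_SAMPLING_END",
    "INDEX_SAMPLING_START",
    "STUDY_CUTOFF",
    "TOY_SCENARIOS",
    "default_params",
    "generate",
    "generate_toy_patient",
    "generate_with_truth",
    "params_from_yaml",
    "params_to_yaml",
]
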