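"""Administrative-claims data model: tables, invariants, and CSV round-trip I/O.

A :class:`ClaimsBundle` holds four linked pandas tables shaped like a
de-identified administrative claims extract:

``patients``
    one row per enrollee: ``patient_id``, ``birth_year``, ``sex``
    (male/female), ``region``, ``insurance`` (commercial or
    medicare_advantage) and an optional ``death_date``.
``enrollment``
    health-plan coverage spans with medical/pharmacy benefit flags.
``medical_claims``
    service-dated claims carrying ordered diagnosis codes (position 1 is
    the primary diagnosis), procedure codes, a place-of-service
    ``setting``, a ``diagnostic_only`` flag for lab/imaging claims, and
    plan/patient paid amounts.
``pharmacy_claims``
    dispensing events: fill date, canonical agent name, strength (mg per
    unit), quantity, days supply, and paid amounts.

Conventions shared by every downstream stage:

* dates are day-granular; all intervals are closed ``[a, b]`` on days;
* money is carried as exact integer cents (``*_paid_cents``) so cost
  aggregation is drift-free;
* diagnosis codes are normalized at read time (upper-cased, dots
  stripped) and carry their code system (ICD9/ICD10) because the study
  window straddles the US ICD transition;
* multi-valued code fields are serialized as ``|``-joined strings.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
import pandas as pd

# ---------------------------------------------------------------------------
# Schema
# ---------------------------------------------------------------------------

SEXES = ("male", "female")
REGIONS = ("Northeast", "Midwest", "South", "West", "Other")
INSURANCE_TYPES = ("commercial", "medicare_advantage")
SETTINGS = ("office", "outpatient", "ed", "inpatient", "other")
CODE_SYSTEMS = ("ICD9", "ICD10")

# column -> kind; kind drives parsing/serialization
# kinds: str, date, date_opt, int, float, bool, cents, enum:<name>
TABLE_SCHEMAS: dict[str, list[tuple[str, str]]] = {
    "patients": [
        ("patient_id", "str"),
        ("birth_year", "int"),
        ("sex", "enum:sex"),
        ("region", "enum:region"),
        ("insurance", "enum:insurance"),
        ("death_date", "date_opt"),
    ],
    "enrollment": [
        ("patient_id", "str"),
        ("start_date", "date"),
        ("end_date", "date"),
        ("medical_benefit", "bool"),
        ("pharmacy_benefit", "bool"),
    ],
    "medical_claims": [
        ("claim_id", "str"),
        ("patient_id", "str"),
        ("service_date", "date"),
        ("end_date", "date"),
        ("dx_codes", "str"),
        ("dx_systems", "str"),
        ("procedure_codes", "str_opt"),
        ("setting", "enum:setting"),
        ("diagnostic_only", "bool"),
        ("plan_paid_cents", "cents"),
        ("patient_paid_cents", "cents"),
    ],
    "pharmacy_claims": [
        ("claim_id", "str"),
        ("patient_id", "str"),
        ("fill_date", "date"),
        ("agent", "str"),
        ("strength_mg", "float"),
        ("quantity", "float"),
        ("days_supply", "int"),
        ("plan_paid_cents", "cents"),
        ("patient_paid_cents", "cents"),
    ],
}

_ENUMS = {
    "sex": SEXES,
    "region": REGIONS,
    "insurance": INSURANCE_TYPES,
    "setting": SETTINGS,
}

TABLE_FILES = {name: f"{name}.csv" for name in TABLE_SCHEMAS}


class ClaimsModelError(ValueError):
    """Fatal data-model error (missing table, unparseable field, bad enum)."""


def normalize_code(code: str) -> str:
    """Normalize a diagnosis/procedure code: upper-case, strip dots and spaces."""
    return str(code).strip().upper().replace(".", "")


def split_codes(joined: str) -> list[str]:
    """Split a ``|``-joined code field into a list (empty string -> [])."""
    if joined is None or (isinstance(joined, float) and np.isnan(joined)):
        return []
    s = str(joined)
    return [c for c in s.split("|") if c] if s else []


def join_codes(codes: Iterable[str]) -> str:
    return "|".join(codes)


# ---------------------------------------------------------------------------
# Bundle container
# ---------------------------------------------------------------------------


@dataclass
class ClaimsBundle:
    """The four linked claims tables. Construction does not validate;
    call :func:`validate_bundle` for the full invariant check."""

    patients: pd.DataFrame
    enrollment: pd.DataFrame
    medical_claims: pd.DataFrame
    pharmacy_claims: pd.DataFrame

    def table(self, name: str) -> pd.DataFrame:
        return getattr(self, name)

    @property
    def n_patients(self) -> int:
        return len(self.patients)

    def copy(self) -> "ClaimsBundle":
        return ClaimsBundle(
            self.patients.copy(),
            self.enrollment.copy(),
            self.medical_claims.copy(),
            self.pharmacy_claims.copy(),
        )


def empty_bundle() -> ClaimsBundle:
    """A bundle with four empty, correctly-typed tables."""
    frames = {}
    for name, schema in TABLE_SCHEMAS.items():
        data = {}
        for col, kind in schema:
            if kind in ("date", "date_opt"):
                data[col] = pd.Series(dtype="datetime64[ns]")
            elif kind in ("int", "cents"):
                data[col] = pd.Series(dtype="int64")
            elif kind == "float":
                data[col] = pd.Series(dtype="float64")
            elif kind == "bool":
                data[col] = pd.Series(dtype="bool")
            else:
                data[col] = pd.Series(dtype="object")
        frames[name] = pd.DataFrame(data)
    return ClaimsBundle(**frames)


# ---------------------------------------------------------------------------
# Read / write
# ---------------------------------------------------------------------------


def _parse_column(tab: str, col: str, kind: str, s: pd.Series) -> pd.Series:
    def fatal(mask: pd.Series, why: str):
        bad = s[mask]
        row = int(bad.index[0])
        raise ClaimsModelError(
            f"{tab}.{col} row {row}: {why} (value {bad.iloc[0]!r})"
        )

    if kind in ("str", "str_opt"):
        out = s.fillna("").astype(str)
        if kind == "str" and col != "dx_codes":  # dx emptiness is a validation, not parse, issue
            pass
        return out
    if kind in ("date", "date_opt"):
        out = pd.to_datetime(s, format="%Y-%m-%d", errors="coerce")
        bad = out.isna() & s.notna() & (s.astype(str).str.len() > 0)
        if bad.any():
            fatal(bad, "unparseable ISO date")
        if kind == "date" and out.isna().any():
            fatal(out.isna(), "missing required date")
        return out
    if kind in ("int", "cents"):
        num = pd.to_numeric(s, errors="coerce")
        bad = num.isna() | (num != num.round())
        if bad.any():
            fatal(bad, "unparseable integer")
        return num.astype("int64")
    if kind == "float":
        num = pd.to_numeric(s, errors="coerce")
        if num.isna().any():
            fatal(num.isna(), "unparseable number")
        return num.astype("float64")
    if kind == "bool":
        mapped = s.astype(str).str.strip().str.lower().map(
            {"true": True, "false": False, "1": True, "0": False}
        )
        if mapped.isna().any():
            fatal(mapped.isna(), "unparseable boolean")
        return mapped.astype(bool)
    if kind.startswith("enum:"):
        allowed = _ENUMS[kind.split(":", 1)[1]]
        out = s.astype(str)
        bad = ~out.isin(allowed)
        if bad.any():
            fatal(bad, f"unknown value, expected one of {allowed}")
        return out
    raise AssertionError(kind)


def read_bundle(directory: str | os.PathLike) -> ClaimsBundle:
    """Read the four claims tables from ``directory``.

    Dates are parsed to day granularity, money to integer cents, and
    diagnosis codes normalized (upper-case, dots stripped). A missing
    table, unparseable field, or unknown enum value is fatal.
    """
    frames = {}
    for name, schema in TABLE_SCHEMAS.items():
        path = os.path.join(directory, TABLE_FILES[name])
        if not os.path.exists(path):
            raise ClaimsModelError(f"missing table file: {TABLE_FILES[name]}")
        raw = pd.read_csv(path, dtype=str, keep_default_na=False)
        raw = raw.replace({"": None}) if name == "patients" else raw
        cols = [c for c, _ in schema]
        missing = set(cols) - set(raw.columns)
        if missing:
            raise ClaimsModelError(f"{name}: missing columns {sorted(missing)}")
        parsed = {}
        for col, kind in schema:
            src = raw[col]
            if kind in ("str", "str_opt", "bool") or kind.startswith("enum:"):
                src = src.fillna("")
            parsed[col] = _parse_column(name, col, kind, src)
        frames[name] = pd.DataFrame(parsed)

    med = frames["medical_claims"]
    if len(med):
        med["dx_codes"] = med["dx_codes"].map(
            lambda v: join_codes(normalize_code(c) for c in split_codes(v))
        )
        med["procedure_codes"] = med["procedure_codes"].map(
            lambda v: join_codes(normalize_code(c) for c in split_codes(v))
        )
    return ClaimsBundle(**frames)


def write_bundle(bundle: ClaimsBundle, directory: str | os.PathLike) -> dict[str, str]:
    """Write the four tables as UTF-8 CSV with ISO-8601 dates and a stable
    column order. Returns ``{table name: file path}``."""
    os.makedirs(directory, exist_ok=True)
    paths = {}
    for name, schema in TABLE_SCHEMAS.items():
        df = bundle.table(name)
        out = pd.DataFrame(index=df.index)
        for col, kind in schema:
            s = df[col]
            if kind in ("date", "date_opt"):
                out[col] = pd.to_datetime(s).dt.strftime("%Y-%m-%d")
                if kind == "date_opt":
                    out[col] = out[col].fillna("")
            elif kind == "bool":
                out[col] = s.map({True: "true", False: "false"})
            else:
                out[col] = s
        path = os.path.join(directory, TABLE_FILES[name])
        out.to_csv(path, index=False)
        paths[name] = path
    return paths


# ---------------------------------------------------------------------------
# Validation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Violation:
    table: str
    row: int | None
    rule: str
    message: str


@dataclass
class ValidationReport:
    violations: list[Violation] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.violations

    def add(self, table: str, row: int | None, rule: str, message: str):
        self.violations.append(Violation(table, row, rule, message))

    def __len__(self) -> int:
        return len(self.violations)

    def __iter__(self):
        return iter(self.violations)


def validate_bundle(bundle: ClaimsBundle) -> ValidationReport:
    """Check every type invariant and referential integrity.

    Violations are data, not exceptions; the report is empty iff the
    bundle is internally consistent.
    """
    rep = ValidationReport()
    pats = bundle.patients
    known = set(pats["patient_id"])

    dup = pats["patient_id"].duplicated()
    for i in pats.index[dup]:
        rep.add("patients", int(i), "unique_patient_id",
                f"duplicate patient_id {pats.at[i, 'patient_id']!r}")

    # ---- enrollment
    enr = bundle.enrollment
    for i in enr.index[enr["end_date"] < enr["start_date"]]:
        rep.add("enrollment", int(i), "span_order", "start_date > end_date")
    for pid, grp in enr.groupby("patient_id", sort=False):
        g = grp.sort_values("start_date")
        prev_end = None
        for i, row in g.iterrows():
            if prev_end is not None and row["start_date"] <= prev_end:
                rep.add("enrollment", int(i), "span_overlap",
                        f"overlapping spans for patient {pid}")
            prev_end = max(prev_end, row["end_date"]) if prev_end is not None else row["end_date"]
    for i in enr.index[~enr["patient_id"].isin(known)]:
        rep.add("enrollment", int(i), "referential_integrity",
                f"unknown patient_id {enr.at[i, 'patient_id']!r}")

    # ---- medical claims
    med = bundle.medical_claims
    for i in med.index[med["end_date"] < med["service_date"]]:
        rep.add("medical_claims", int(i), "claim_dates", "end_date < service_date")
    for i in med.index[med["dx_codes"].map(lambda v: len(split_codes(v)) == 0)]:
        rep.add("medical_claims", int(i), "dx_nonempty", "claim has no diagnosis codes")
    if len(med):
        bad_sys = med.apply(
            lambda r: any(s not in CODE_SYSTEMS for s in split_codes(r["dx_systems"]))
            or len(split_codes(r["dx_systems"])) != len(split_codes(r["dx_codes"])),
            axis=1,
        )
        for i in med.index[bad_sys]:
            rep.add("medical_claims", int(i), "dx_systems",
                    "dx_systems must parallel dx_codes with ICD9/ICD10 entries")
    for col in ("plan_paid_cents", "patient_paid_cents"):
        for i in med.index[med[col] < 0]:
            rep.add("medical_claims", int(i), "nonnegative_paid", f"{col} < 0")
    for i in med.index[~med["patient_id"].isin(known)]:
        rep.add("medical_claims", int(i), "referential_integrity",
                f"unknown patient_id {med.at[i, 'patient_id']!r}")

    # ---- pharmacy claims
    rx = bundle.pharmacy_claims
    for i in rx.index[rx["days_supply"] < 1]:
        rep.add("pharmacy_claims", int(i), "days_supply", "days_supply < 1")
    for i in rx.index[(rx["strength_mg"] * rx["quantity"]) <= 0]:
        rep.add("pharmacy_claims", int(i), "dispensed_dose", "strength_mg x quantity <= 0")
    for col in ("plan_paid_cents", "patient_paid_cents"):
        for i in rx.index[rx[col] < 0]:
            rep.add("pharmacy_claims", int(i), "nonnegative_paid", f"{col} < 0")
    for i in rx.index[~rx["patient_id"].isin(known)]:
        rep.add("pharmacy_claims", int(i), "referential_integrity",
                f"unknown patient_id {rx.at[i, 'patient_id']!r}")

    # ---- age >= 0 at any claim date
    if len(pats):
        by = pats.drop_duplicates("patient_id").set_index("patient_id")["birth_year"]
        for tab, datecol in (("medical_claims", "service_date"), ("pharmacy_claims", "fill_date")):
            df = bundle.table(tab)
            if not len(df):
                continue
            yr = df[datecol].dt.year
            byear = df["patient_id"].map(by)
            for i in df.index[(byear.notna()) & (yr < byear)]:
                rep.add(tab, int(i), "age_nonnegative",
                        "claim predates patient birth year")
    return rep


__all__ = [
    "ClaimsBundle",
    "ClaimsModelError",
    "ValidationReport",
    "Violation",
    "empty_bundle",
    "join_codes",
    "normalize_code",
    "read_bundle",
    "split_codes",
    "validate_bundle",
    "SEXES",
    "REGIONS",
    "INSURANCE_TYPES",
    "SETTINGS",
    "TABLE_SCHEMAS",
    "write_bundle",
]
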