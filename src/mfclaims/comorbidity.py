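"""Pre-index comorbidity burden: Charlson Comorbidity Index and AHRQ flags.

The Charlson Comorbidity Index (CCI) is computed with the Quan (2005)
ICD-9-CM / ICD-10 coding-algorithm mapping and the original Charlson
weights (1/2/3/6). Each condition counts once regardless of how many
codes hit it, and the standard hierarchy rules apply: complicated
diabetes supersedes uncomplicated, metastatic solid tumor supersedes
non-metastatic malignancy, and moderate/severe liver disease supersedes
mild liver disease. Unmapped codes contribute nothing.

AHRQ comorbidity categories are reduced to code-prefix lists (the
packaged table names the eight categories the analysis reports); a
category is flagged iff at least one observed code matches one of its
prefixes. Both mapping tables ship as editable CSVs; patterns may be
single prefixes (``I25.2``) or inclusive ranges (``C00-C26``), expanded
at load time after dot-stripping normalization.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from importlib import resources
from typing import Iterable

import pandas as pd

from .claims_model import ClaimsBundle, normalize_code, split_codes

CHARLSON_TABLE = "charlson_quan2005.csv"
AHRQ_TABLE = "ahrq_categories.csv"

_RANGE_RE = re.compile(r"^([A-Z]*)(\d+)$")


def _expand_pattern(pattern: str) -> list[str]:
    """Expand a single prefix or ``A-B`` inclusive range into prefixes."""
    pattern = str(pattern).strip()
    if "-" not in pattern:
        return [normalize_code(pattern)]
    lo, hi = (normalize_code(p) for p in pattern.split("-", 1))
    m_lo, m_hi = _RANGE_RE.match(lo), _RANGE_RE.match(hi)
    if not (m_lo and m_hi) or m_lo.group(1) != m_hi.group(1) or \
            len(m_lo.group(2)) != len(m_hi.group(2)):
        raise ValueError(f"unexpandable code range {pattern!r}")
    alpha, width = m_lo.group(1), len(m_lo.group(2))
    a, b = int(m_lo.group(2)), int(m_hi.group(2))
    if b < a:
        raise ValueError(f"descending code range {pattern!r}")
    return [f"{alpha}{i:0{width}d}" for i in range(a, b + 1)]


def _data_path(name: str):
    return resources.files("mfclaims").joinpath("data", name)


@dataclass(frozen=True)
class CodeMap:
    """Prefix map: (group, code_system) -> tuple of normalized prefixes."""

    prefixes: dict[tuple[str, str], tuple[str, ...]]
    weights: dict[str, int]  # empty for AHRQ maps

    @property
    def groups(self) -> list[str]:
        seen = []
        for g, _ in self.prefixes:
            if g not in seen:
                seen.append(g)
        return seen

    def match(self, codes: Iterable[tuple[str, str]]) -> set[str]:
        """Groups hit by any (code, system) pair."""
        hit = set()
        norm = [(normalize_code(c), s) for c, s in codes]
        for (group, system), prefs in self.prefixes.items():
            if group in hit:
                continue
            for code, sys_ in norm:
                if sys_ == system and code.startswith(prefs):
                    hit.add(group)
                    break
        return hit


def _load_map(path, group_col: str, with_weights: bool) -> CodeMap:
    df = pd.read_csv(path)
    prefixes: dict[tuple[str, str], list[str]] = {}
    weights: dict[str, int] = {}
    for _, row in df.iterrows():
        key = (row[group_col], row["code_system"])
        prefixes.setdefault(key, []).extend(_expand_pattern(row["pattern"]))
        if with_weights:
            weights[row[group_col]] = int(row["weight"])
    return CodeMap({k: tuple(v) for k, v in prefixes.items()}, weights)


def load_charlson_map(path=None) -> CodeMap:
    """Quan-2005 Charlson mapping with original weights (packaged default)."""
    return _load_map(path or _data_path(CHARLSON_TABLE), "condition", True)


def load_ahrq_map(path=None) -> CodeMap:
    """AHRQ comorbidity-category prefix map (packaged default)."""
    return _load_map(path or _data_path(AHRQ_TABLE), "category", False)


# hierarchy: the first condition, when present, silences the second
CCI_HIERARCHY = (
    ("diabetes_complicated", "diabetes_uncomplicated"),
    ("metastatic_tumor", "malignancy"),
    ("severe_liver", "mild_liver"),
)


def compute_cci(codes: Iterable[tuple[str, str]], charlson: CodeMap | None = None) -> int:
    """Charlson Comorbidity Index over observed (code, system) pairs."""
    charlson = charlson or load_charlson_map()
    conditions = charlson.match(codes)
    for winner, loser in CCI_HIERARCHY:
        if winner in conditions:
            conditions.discard(loser)
    return sum(charlson.weights[c] for c in conditions)


def flag_ahrq(codes: Iterable[tuple[str, str]], ahrq: CodeMap | None = None) -> dict[str, bool]:
    """Boolean flag per AHRQ category: ≥1 code matches a category prefix."""
    ahrq = ahrq or load_ahrq_map()
    hits = ahrq.match(codes)
    return {cat: cat in hits for cat in ahrq.groups}


def _patient_codes(medical_claims: pd.DataFrame,
                   start: pd.Timestamp, end: pd.Timestamp) -> list[tuple[str, str]]:
    df = medical_claims
    df = df[(df["service_date"] >= start) & (df["service_date"] <= end)]
    out: list[tuple[str, str]] = []
    for _, row in df.iterrows():
        out.extend(zip(split_codes(row["dx_codes"]), split_codes(row["dx_systems"])))
    return out


def profile_cohort(
    bundle: ClaimsBundle,
    members: pd.DataFrame,
    lookback_days: int = 365,
    charlson: CodeMap | None = None,
    ahrq: CodeMap | None = None,
) -> pd.DataFrame:
    """Comorbidity profile per cohort member over the pre-index lookback
    window ``[index - lookback_days, index - 1]``.

    Returns one row per member: ``patient_id``, ``cci_score``,
    ``cci_ge5``, and one boolean column per AHRQ category.
    """
    charlson = charlson or load_charlson_map()
    ahrq = ahrq or load_ahrq_map()
    med_by_pid = dict(tuple(bundle.medical_claims.groupby("patient_id", sort=False)))
    empty_med = bundle.medical_claims.iloc[0:0]
    rows = []
    for _, r in members.iterrows():
        idx = r["index_date"]
        codes = _patient_codes(
            med_by_pid.get(r["patient_id"], empty_med),
            idx - pd.Timedelta(days=lookback_days),
            idx - pd.Timedelta(days=1),
        )
        cci = compute_cci(codes, charlson)
        row = {"patient_id": r["patient_id"], "cci_score": cci, "cci_ge5": cci >= 5}
        row.update(flag_ahrq(codes, ahrq))
        rows.append(row)
    cols = ["patient_id", "cci_score", "cci_ge5"] + ahrq.groups
    return pd.DataFrame(rows, columns=cols)


__all__ = [
    "CodeMap",
    "CCI_HIERARCHY",
    "compute_cci",
    "flag_ahrq",
    "load_ahrq_map",
    "load_charlson_map",
    "profile_cohort",
]
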