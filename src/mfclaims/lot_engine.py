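"""Line-of-therapy (LOT) derivation from post-index treatment events.

The first two LOTs per patient are reconstructed with a rule set common
to oncology claims analyses:

* **start** — the first claim for a listed MF agent or other systemic
  anti-cancer therapy (pharmacy fill or medical administration), or a
  transplantation/splenectomy procedure, on or after the index MF date;
* **regimen** — every listed agent with an event inside the first 30
  days of the line (``[start, start + 29]``); a single agent is
  monotherapy, more a combination;
* **end** — the earliest of: a *switch* (first event for an agent
  outside the regimen dated ≥ start + 30; the line ends the day
  before), a *discontinuation* (supply run-out with no regimen-agent
  event inside the next 45 days; the line ends at the run-out),
  *transplantation or splenectomy*, *death*, or *censoring* at
  follow-up end (disenrollment or study cut-off). Ties break
  transplant/splenectomy > death > switch > discontinuation > censor.
* **line 2** — restarts the same rules at the first qualifying event
  after the line-1 end date; lines beyond 2 are not derived.

Pharmacy fills cover ``[fill, fill + days_supply - 1]``. Agents
administered on medical claims (azacitidine/decitabine infusions) carry
an imputed 1-day supply but a configurable persistence window (default
28 days per administration) so cycle-based drugs are not spuriously
discontinued. A run-out whose 45-day gap cannot be fully observed
before follow-up end is treated as censoring, not discontinuation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .claims_model import ClaimsBundle, split_codes

# ---------------------------------------------------------------------------
# Agent taxonomy
# ---------------------------------------------------------------------------

NCCN_MF_AGENTS = frozenset({
    "ruxolitinib", "fedratinib", "hydroxyurea", "peginterferon alfa-2a",
    "interferon alfa-2b", "danazol", "thalidomide", "lenalidomide",
    "pomalidomide", "azacitidine", "decitabine",
})
OTHER_SYSTEMIC_AGENTS = frozenset({
    "melphalan", "busulfan", "cladribine", "cytarabine", "imatinib",
})
# agents delivered on medical claims (HCPCS J-codes), not pharmacy fills
MEDICAL_ADMIN_PROCEDURES = {"J9025": "azacitidine", "J0894": "decitabine"}
TRANSPLANT_PROCEDURES = frozenset({"38240", "38241"})
SPLENECTOMY_PROCEDURES = frozenset({"38100", "38101", "38102", "38120"})

END_REASON_PRIORITY = {
    "transplant_or_splenectomy": 0,
    "death": 1,
    "switch": 2,
    "discontinuation": 3,
    "censored": 4,
}


@dataclass(frozen=True)
class LotConfig:
    regimen_window_days: int = 30
    gap_days: int = 45
    nccn_agents: frozenset = NCCN_MF_AGENTS
    systemic_agents: frozenset = OTHER_SYSTEMIC_AGENTS
    medical_admin_procedures: dict = field(
        default_factory=lambda: dict(MEDICAL_ADMIN_PROCEDURES))
    transplant_procedures: frozenset = TRANSPLANT_PROCEDURES
    splenectomy_procedures: frozenset = SPLENECTOMY_PROCEDURES
    imputed_supply_for_medical_admin: int = 1
    medical_admin_persistence_days: int = 28

    @property
    def listed_agents(self) -> frozenset:
        return self.nccn_agents | self.systemic_agents

    def agent_category(self, agent: str) -> str:
        return "nccn_mf_agent" if agent in self.nccn_agents else "other_systemic"


@dataclass(frozen=True)
class AgentEvent:
    """One dated treatment event (day-ordinal dates for arithmetic)."""

    patient_id: str
    day: int                # proleptic-Gregorian ordinal
    agent: str              # canonical name, or TRANSPLANT/SPLENECTOMY
    category: str           # nccn_mf_agent/other_systemic/transplant/splenectomy
    source: str             # pharmacy/medical
    days_supply: int
    coverage_days: int      # days this event covers from its date


@dataclass
class LineOfTherapy:
    patient_id: str
    line_number: int
    start_day: int
    end_day: int
    regimen: frozenset
    end_reason: str

    @property
    def complete(self) -> bool:
        return self.end_reason != "censored"

    @property
    def duration_days(self) -> int:
        return self.end_day - self.start_day + 1

    @property
    def start_date(self) -> pd.Timestamp:
        return pd.Timestamp.fromordinal(self.start_day)

    @property
    def end_date(self) -> pd.Timestamp:
        return pd.Timestamp.fromordinal(self.end_day)


def _ordinal(ts) -> int:
    if isinstance(ts, (int, np.integer)):
        return int(ts)
    return pd.Timestamp(ts).toordinal()


_CAT_ORDER = {"nccn_mf_agent": 0, "other_systemic": 1, "transplant": 2, "splenectomy": 3}


def extract_agent_events(
    bundle: ClaimsBundle,
    patient_id: str,
    index_mf_date,
    config: LotConfig = LotConfig(),
) -> list[AgentEvent]:
    """All LOT-relevant events for one patient on/after the index MF date,
    sorted by (date, category, agent)."""
    idx = _ordinal(index_mf_date)
    events: list[AgentEvent] = []

    rx = bundle.pharmacy_claims
    rx = rx[(rx["patient_id"] == patient_id) & rx["agent"].isin(config.listed_agents)]
    for _, row in rx.iterrows():
        day = _ordinal(row["fill_date"])
        if day < idx:
            continue
        ds = int(row["days_supply"])
        events.append(AgentEvent(patient_id, day, row["agent"],
                                 config.agent_category(row["agent"]),
                                 "pharmacy", ds, ds))

    med = bundle.medical_claims
    med = med[med["patient_id"] == patient_id]
    for _, row in med.iterrows():
        day = _ordinal(row["service_date"])
        if day < idx:
            continue
        procs = split_codes(row["procedure_codes"])
        for p in procs:
            if p in config.medical_admin_procedures:
                agent = config.medical_admin_procedures[p]
                events.append(AgentEvent(
                    patient_id, day, agent, config.agent_category(agent),
                    "medical", config.imputed_supply_for_medical_admin,
                    config.medical_admin_persistence_days))
            elif p in config.transplant_procedures:
                events.append(AgentEvent(patient_id, day, "TRANSPLANT",
                                         "transplant", "medical", 0, 0))
            elif p in config.splenectomy_procedures:
                events.append(AgentEvent(patient_id, day, "SPLENECTOMY",
                                         "splenectomy", "medical", 0, 0))

    events.sort(key=lambda e: (e.day, _CAT_ORDER[e.category], e.agent))
    return events


def _derive_one_line(
    events: list[AgentEvent],
    follow_up_end: int,
    death_day: int | None,
    config: LotConfig,
    line_number: int,
) -> LineOfTherapy:
    first = events[0]
    pid = first.patient_id
    s = first.day

    if first.category in ("transplant", "splenectomy"):
        # procedure as the line-starting event: starts and ends the line
        return LineOfTherapy(pid, line_number, s, s, frozenset({first.agent}),
                             "transplant_or_splenectomy")

    window_end = s + config.regimen_window_days - 1
    regimen = frozenset(
        e.agent for e in events
        if e.category in ("nccn_mf_agent", "other_systemic") and s <= e.day <= window_end
    )

    candidates: list[tuple[int, str]] = []

    # (a) switch: first event for an out-of-regimen agent dated >= s + 30
    for e in events:
        if (e.category in ("nccn_mf_agent", "other_systemic")
                and e.agent not in regimen and e.day >= s + config.regimen_window_days):
            candidates.append((e.day - 1, "switch"))
            break

    # (b) discontinuation: supply run-out followed by a > gap_days hole
    reg_events = [e for e in events if e.agent in regimen]
    covered_end = reg_events[0].day + reg_events[0].coverage_days - 1
    runout = None
    for e in reg_events[1:]:
        if e.day > covered_end + config.gap_days:
            runout = covered_end
            break
        covered_end = max(covered_end, e.day + e.coverage_days - 1)
    if runout is None:
        runout = covered_end
    # the full gap must be observable inside follow-up, else censoring
    if runout + config.gap_days < follow_up_end:
        candidates.append((runout, "discontinuation"))

    # (c) transplantation or splenectomy
    for e in events:
        if e.category in ("transplant", "splenectomy"):
            candidates.append((e.day, "transplant_or_splenectomy"))
            break

    # (d) death
    if death_day is not None and death_day <= follow_up_end:
        candidates.append((death_day, "death"))

    # (e) censoring at follow-up end
    candidates.append((follow_up_end, "censored"))

    end_day, reason = min(candidates, key=lambda c: (c[0], END_REASON_PRIORITY[c[1]]))
    end_day = max(end_day, s)  # a switch the day after start cannot pre-date the start
    return LineOfTherapy(pid, line_number, s, end_day, regimen, reason)


def derive_lots(
    events: list[AgentEvent],
    follow_up_end,
    death_date=None,
    config: LotConfig = LotConfig(),
) -> list[LineOfTherapy]:
    """Derive up to two lines of therapy from sorted agent events.

    ``follow_up_end`` is min(disenrollment, study cut-off); events after
    it (or after death) are ignored. Returns 0, 1 or 2 lines.
    """
    f_end = _ordinal(follow_up_end)
    d_day = _ordinal(death_date) if death_date is not None and not pd.isna(death_date) else None
    horizon = f_end if d_day is None else min(f_end, d_day)
    evs = [e for e in events if e.day <= horizon]
    if not evs:
        return []

    lots = [_derive_one_line(evs, f_end, d_day, config, 1)]
    if lots[0].end_reason == "death":
        return lots
    rest = [e for e in evs if e.day > lots[0].end_day]
    if rest:
        lots.append(_derive_one_line(rest, f_end, d_day, config, 2))
    return lots


# ---------------------------------------------------------------------------
# Regimen categorization and cohort-level summary
# ---------------------------------------------------------------------------

REGIMEN_CATEGORIES = (
    "rux_monotherapy", "rux_combination", "hydroxyurea_monotherapy",
    "aza_dec_monotherapy", "other",
)


def categorize_regimen(regimen: frozenset) -> str:
    if regimen == frozenset({"ruxolitinib"}):
        return "rux_monotherapy"
    if "ruxolitinib" in regimen:
        return "rux_combination"
    if regimen == frozenset({"hydroxyurea"}):
        return "hydroxyurea_monotherapy"
    if regimen in (frozenset({"azacitidine"}), frozenset({"decitabine"})):
        return "aza_dec_monotherapy"
    return "other"


@dataclass
class LotSummary:
    """Treatment-pattern table: per-line regimen mix, completeness,
    durations of complete lines, and end reasons."""

    n_with_lot1: int
    n_with_lot2: int
    per_line: pd.DataFrame       # long: line, measure, category, n, pct/value

    def line_table(self, line_number: int) -> pd.DataFrame:
        return self.per_line[self.per_line["line"] == line_number]


def lots_to_frame(lots: list[LineOfTherapy]) -> pd.DataFrame:
    rows = [{
        "patient_id": l.patient_id,
        "line_number": l.line_number,
        "start_date": l.start_date,
        "end_date": l.end_date,
        "regimen": "|".join(sorted(l.regimen)),
        "regimen_category": categorize_regimen(l.regimen),
        "end_reason": l.end_reason,
        "complete": l.complete,
        "duration_days": l.duration_days,
    } for l in lots]
    return pd.DataFrame(rows, columns=[
        "patient_id", "line_number", "start_date", "end_date", "regimen",
        "regimen_category", "end_reason", "complete", "duration_days"])


def summarize_lots(lots: list[LineOfTherapy] | pd.DataFrame) -> LotSummary:
    df = lots if isinstance(lots, pd.DataFrame) else lots_to_frame(lots)
    n1 = int((df["line_number"] == 1).sum())
    n2 = int((df["line_number"] == 2).sum())
    rows = []
    for line in (1, 2):
        sub = df[df["line_number"] == line]
        n = len(sub)
        for cat in REGIMEN_CATEGORIES:
            k = int((sub["regimen_category"] == cat).sum())
            rows.append({"line": line, "measure": "regimen", "category": cat,
                         "n": k, "value": 100.0 * k / n if n else np.nan})
        k = int(sub["complete"].sum())
        rows.append({"line": line, "measure": "complete", "category": "complete",
                     "n": k, "value": 100.0 * k / n if n else np.nan})
        dur = sub.loc[sub["complete"], "duration_days"]
        rows.append({"line": line, "measure": "duration_complete_mean",
                     "category": "days", "n": len(dur),
                     "value": float(dur.mean()) if len(dur) else np.nan})
        rows.append({"line": line, "measure": "duration_complete_sd",
                     "category": "days", "n": len(dur),
                     "value": float(dur.std(ddof=1)) if len(dur) > 1 else np.nan})
        for reason in END_REASON_PRIORITY:
            k = int((sub["end_reason"] == reason).sum())
            rows.append({"line": line, "measure": "end_reason", "category": reason,
                         "n": k, "value": 100.0 * k / n if n else np.nan})
    return LotSummary(n1, n2, pd.DataFrame(rows))


__all__ = [
    "AgentEvent",
    "END_REASON_PRIORITY",
    "LineOfTherapy",
    "LotConfig",
    "LotSummary",
    "MEDICAL_ADMIN_PROCEDURES",
    "NCCN_MF_AGENTS",
    "OTHER_SYSTEMIC_AGENTS",
    "REGIMEN_CATEGORIES",
    "SPLENECTOMY_PROCEDURES",
    "TRANSPLANT_PROCEDURES",
    "categorize_regimen",
    "derive_lots",
    "extract_agent_events",
    "lots_to_frame",
    "summarize_lots",
]
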