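"""Independent brute-force oracle for line-of-therapy derivation.

Recomputes LOT boundaries with a day-grid state machine: coverage is
materialized as a boolean day array and discontinuation found as the
first uncovered run longer than the gap, instead of the engine's
interval-chaining. Used to cross-check ``derive_lots`` over an
exhaustive enumeration of short event sequences.
"""

from __future__ import annotations

from itertools import combinations, product

import numpy as np

from mfclaims.lot_engine import AgentEvent, LineOfTherapy

PRIORITY = {"transplant_or_splenectomy": 0, "death": 1, "switch": 2,
            "discontinuation": 3, "censored": 4}


def _oracle_line(evs, f_end, death, gap, window, num):
    first = evs[0]
    s = first.day
    if first.category in ("transplant", "splenectomy"):
        return LineOfTherapy(first.patient_id, num, s, s,
                             frozenset({first.agent}), "transplant_or_splenectomy")
    regimen = frozenset(
        e.agent for e in evs
        if e.category in ("nccn_mf_agent", "other_systemic") and e.day < s + window)

    cands = []
    for e in evs:
        if (e.category in ("nccn_mf_agent", "other_systemic")
                and e.agent not in regimen and e.day >= s + window):
            cands.append((e.day - 1, "switch"))
            break
    for e in evs:
        if e.category in ("transplant", "splenectomy"):
            cands.append((e.day, "transplant_or_splenectomy"))
            break
    if death is not None and death <= f_end:
        cands.append((death, "death"))

    # discontinuation on a literal day grid
    reg = [e for e in evs if e.agent in regimen]
    hi = max(e.day + e.coverage_days for e in reg) + gap + 2
    covered = np.zeros(hi - s + 1, dtype=bool)
    for e in reg:
        covered[e.day - s: e.day - s + e.coverage_days] = True
    run = 0
    runout = None
    for i in range(len(covered)):
        if covered[i]:
            run = 0
        else:
            run += 1
            if run == gap + 1:
                runout = s + i - run
                break
    assert runout is not None  # the array extends gap+2 past last coverage
    if runout + gap < f_end:
        cands.append((runout, "discontinuation"))

    cands.append((f_end, "censored"))
    end, reason = min(cands, key=lambda c: (c[0], PRIORITY[c[1]]))
    return LineOfTherapy(first.patient_id, num, s, max(end, s), regimen, reason)


def oracle_derive(events, follow_up_end: int, death_day: int | None = None,
                  gap: int = 45, window: int = 30):
    """Brute-force LOT derivation (≤2 lines) over integer-day events."""
    horizon = follow_up_end if death_day is None else min(follow_up_end, death_day)
    evs = [e for e in events if e.day <= horizon]
    lines = []
    while evs and len(lines) < 2:
        line = _oracle_line(evs, follow_up_end, death_day, gap, window, len(lines) + 1)
        lines.append(line)
        if line.end_reason == "death":
            break
        evs = [e for e in evs if e.day > line.end_day]
    return lines


# ---------------------------------------------------------------------------
# Exhaustive enumeration of short event sequences
# ---------------------------------------------------------------------------

DAY_GRID = (0, 20, 40, 60, 90, 140, 200)
FOLLOW_UP_END = 230
KINDS = ("A", "B", "T", "D")  # two 30-day-supply agents, transplant, death


def enumerate_cases(max_events: int = 4, grid=DAY_GRID):
    """Yield (days, kinds) for every sequence of ≤max_events with at most
    one transplant and one death."""
    for n in range(1, max_events + 1):
        for days in combinations(grid, n):
            for kinds in product(KINDS, repeat=n):
                if kinds.count("T") > 1 or kinds.count("D") > 1:
                    continue
                yield days, kinds


def build_case(days, kinds, pid="X"):
    """Materialize a case as (events, death_day)."""
    events = []
    death = None
    for d, k in zip(days, kinds):
        if k == "D":
            death = d
        elif k == "T":
            events.append(AgentEvent(pid, d, "TRANSPLANT", "transplant",
                                     "medical", 0, 0))
        else:
            agent = "hydroxyurea" if k == "A" else "ruxolitinib"
            events.append(AgentEvent(pid, d, agent, "nccn_mf_agent",
                                     "pharmacy", 30, 30))
    return events, death


def line_key(line: LineOfTherapy):
    return (line.line_number, line.start_day, line.end_day,
            frozenset(line.regimen), line.end_reason)
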