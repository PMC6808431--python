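"""Aggregation of ICD-10 event records into incident/prevalent outcomes.

Registry records (hospital discharge diagnoses and deaths, main and side
diagnoses treated equally) are matched to outcome definitions — a single
three-digit ICD-10 code or an inclusive range such as I70–I79 — and
aggregated per person into:

* incident status: first matching event within (baseline age,
  baseline age + follow-up]; its age becomes the exit time;
* prevalent status: any matching event at or before baseline age
  (an event exactly at baseline counts as prevalent, not incident);
* censoring age: baseline age + follow-up for event-free persons.

Eligibility for association testing requires at least ``min_incident``
incident cases in *every* cohort; prevalent-case adjustment is switched
on per cohort when there are at least ``min_prevalent_adjust`` prevalent
cases. Both counts are taken within the subset of persons for whom the
biomarker under study was successfully imputed.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "OutcomeDefinition",
    "match_code",
    "aggregate",
    "eligibility",
    "validate_icd10",
]

_ICD10_RE = re.compile(r"^[A-Z][0-9]{2}")
_ICD9_RE = re.compile(r"^[0-9]{3}")


@dataclass(frozen=True)
class OutcomeDefinition:
    """One outcome: a 3-digit ICD-10 code or an inclusive code range."""

    label: str
    code_start: str  # e.g. "I50" or range start "I70"
    code_end: str | None = None  # range end "I79"; None for a single code

    def __post_init__(self):
        for c in (self.code_start, self.code_end):
            if c is not None and not _ICD10_RE.match(c):
                raise ValueError(f"invalid 3-digit ICD-10 code {c!r} in {self.label!r}")
        if self.code_end is not None and self.code_end < self.code_start:
            raise ValueError(f"range start {self.code_start} > end {self.code_end}")

    @classmethod
    def parse(cls, label: str, spec: str) -> "OutcomeDefinition":
        """Parse 'I50' or 'I70-I79' (en dash accepted)."""
        spec = spec.replace("–", "-").strip()
        if "-" in spec:
            a, b = spec.split("-")
            return cls(label, a.strip(), b.strip())
        return cls(label, spec)

    @property
    def spec(self) -> str:
        return self.code_start if self.code_end is None else f"{self.code_start}-{self.code_end}"


def validate_icd10(code: str) -> str:
    """Check an ICD-10 code; reject ICD-9-looking (all-numeric) codes."""
    code = str(code).strip().upper()
    if _ICD9_RE.match(code):
        raise ValueError(
            f"code {code!r} looks like ICD-9; convert to ICD-10 upstream "
            "(e.g. via the CDC General Equivalence Mappings) before loading"
        )
    if not _ICD10_RE.match(code):
        raise ValueError(f"malformed ICD-10 code {code!r}")
    return code


def match_code(code: str, definition: OutcomeDefinition) -> bool:
    """True iff the record's 3-digit prefix falls in the definition."""
    prefix = validate_icd10(code)[:3]
    if definition.code_end is None:
        return prefix == definition.code_start
    return definition.code_start <= prefix <= definition.code_end


def aggregate(
    records: pd.DataFrame,
    definitions: list[OutcomeDefinition],
    baseline_age: pd.Series,
    followup_years: float = 8.0,
) -> pd.DataFrame:
    """Aggregate event records into a per-person × outcome table.

    Parameters
    ----------
    records : DataFrame
        Columns ``person_id``, ``event_age``, ``icd10`` (``source`` is
        ignored: main and side diagnoses count equally).
    baseline_age : Series
        Baseline age per person id; every record's person must appear.

    Returns
    -------
    DataFrame with MultiIndex columns per outcome label:
    ``(label, 'prevalent')``, ``(label, 'incident')``,
    ``(label, 'event_age')`` (exit age: first incident event, else
    baseline + follow-up). Result is invariant to record order.
    """
    persons = baseline_age.index
    unknown = set(records["person_id"]) - set(persons)
    if unknown:
        raise ValueError(f"records reference unknown persons: {sorted(unknown)[:5]}")
    base = baseline_age.to_numpy(dtype=float)
    out = {}
    prefixes = records["icd10"].astype(str).str.strip().str.upper().str[:3]
    pid = records["person_id"].to_numpy()
    age = records["event_age"].to_numpy(dtype=float)
    pos = pd.Series(np.arange(len(persons)), index=persons)
    rec_pos = pos.reindex(pid).to_numpy()
    for d in definitions:
        if d.code_end is None:
            hit = prefixes == d.code_start
        else:
            hit = (prefixes >= d.code_start) & (prefixes <= d.code_end)
        hb = base[rec_pos]
        prev_hit = hit & (age <= hb)
        inc_hit = hit & (age > hb) & (age <= hb + followup_years)
        prevalent = np.zeros(len(persons), dtype=int)
        prevalent[rec_pos[prev_hit]] = 1
        incident = np.zeros(len(persons), dtype=int)
        event_age = base + followup_years
        inc_idx = rec_pos[inc_hit]
        inc_age = age[inc_hit]
        order = np.lexsort((inc_age, inc_idx))[::-1]  # later overwritten by earlier
        incident[inc_idx] = 1
        event_age_tmp = event_age.copy()
        for r in order:
            event_age_tmp[inc_idx[r]] = inc_age[r]
        out[(d.label, "prevalent")] = prevalent
        out[(d.label, "incident")] = incident
        out[(d.label, "event_age")] = event_age_tmp
    table = pd.DataFrame(out, index=persons)
    table.columns = pd.MultiIndex.from_tuples(table.columns, names=["outcome", "field"])
    return table


def eligibility(
    tables: dict[str, pd.DataFrame],
    min_incident: int = 20,
    min_prevalent_adjust: int = 10,
) -> pd.DataFrame:
    """Per-outcome analysis decisions across cohorts.

    Parameters
    ----------
    tables : dict
        Cohort name -> outcome table from :func:`aggregate` (already
        subset to the biomarker's successfully-imputed persons).

    Returns
    -------
    DataFrame indexed by outcome label with columns ``analyse`` (incident
    count ≥ ``min_incident`` in every cohort) and, per cohort,
    ``incident_<cohort>``, ``prevalent_<cohort>``, ``adjust_<cohort>``
    (prevalent count ≥ ``min_prevalent_adjust``).
    """
    if len(tables) < 2:
        raise ValueError("eligibility requires at least two cohorts")
    outcomes = list(next(iter(tables.values())).columns.get_level_values("outcome").unique())
    rows = {}
    for label in outcomes:
        row = {}
        ok = True
        for cohort, tab in tables.items():
            inc = int(tab[(label, "incident")].sum())
            prev = int(tab[(label, "prevalent")].sum())
            row[f"incident_{cohort}"] = inc
            row[f"prevalent_{cohort}"] = prev
            row[f"adjust_{cohort}"] = prev >= min_prevalent_adjust
            ok = ok and inc >= min_incident
        row["analyse"] = ok
        rows[label] = row
    return pd.DataFrame(rows).T
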