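"""Preprocessing of raw generated cohorts into refined cohorts.

Five rules, applied in order per record:

1. drop records lacking the diabetes anchor code or a sex label;
2. drop visits that are empty or carry only age information;
3. per chronic code, keep only its first visit occurrence;
4. within a visit carrying multiple age labels, keep the maximum;
5. a visit lacking an age label gets the arithmetic mean of the adjacent
   visits' ages (boundary visits copy their single neighbor; records with no
   aged visit at all are dropped and counted).

``refine_for_prediction`` adds the two exclusions specific to the endpoint
prediction task: non-ascending visit ages, and endpoint before the anchor.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional, Set

import yaml

from .records import Cohort, PatientRecord, Visit

__all__ = ["DiscardReport", "refine_cohort", "refine_for_prediction"]


@dataclass(frozen=True)
class DiscardReport:
    n_input: int
    n_output: int
    n_no_anchor: int = 0
    n_no_sex: int = 0
    n_no_aged_visit: int = 0
    n_non_ascending: int = 0
    n_endpoint_before_anchor: int = 0

    def _frac(self, k: int) -> float:
        return k / self.n_input if self.n_input else 0.0

    @property
    def fraction_no_anchor(self) -> float:
        return self._frac(self.n_no_anchor)

    @property
    def fraction_no_sex(self) -> float:
        return self._frac(self.n_no_sex)

    @property
    def fraction_no_aged_visit(self) -> float:
        return self._frac(self.n_no_aged_visit)

    @property
    def fraction_non_ascending(self) -> float:
        return self._frac(self.n_non_ascending)

    @property
    def fraction_endpoint_before_anchor(self) -> float:
        return self._frac(self.n_endpoint_before_anchor)

    @property
    def fraction_total_discarded(self) -> float:
        return (self.n_input - self.n_output) / self.n_input if self.n_input else 0.0

    def to_dict(self) -> dict:
        return {
            "n_input": self.n_input,
            "n_output": self.n_output,
            "n_no_anchor": self.n_no_anchor,
            "n_no_sex": self.n_no_sex,
            "n_no_aged_visit": self.n_no_aged_visit,
            "n_non_ascending": self.n_non_ascending,
            "n_endpoint_before_anchor": self.n_endpoint_before_anchor,
            "fraction_no_anchor": self.fraction_no_anchor,
            "fraction_no_sex": self.fraction_no_sex,
            "fraction_non_ascending": self.fraction_non_ascending,
            "fraction_endpoint_before_anchor": self.fraction_endpoint_before_anchor,
            "fraction_total_discarded": self.fraction_total_discarded,
        }

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh)


def _refine_record(record: PatientRecord, chronic: Set[str]) -> Optional[PatientRecord]:
    # rule 2: drop empty / age-only visits
    visits = [v for v in record.visits if v.codes]
    # rule 3: first occurrence per chronic code (by visit order)
    seen: Set[str] = set()
    cleaned = []
    for v in visits:
        keep = frozenset(c for c in v.codes if not (c in chronic and c in seen))
        seen |= v.codes & chronic
        if keep:
            cleaned.append(replace(v, codes=keep))
    # rule 4: multiple age labels -> keep the maximum
    cleaned = [
        replace(v, ages=(max(v.ages),)) if len(v.ages) > 1 else v for v in cleaned
    ]
    # rule 5: impute missing ages from neighbors (boundaries copy the neighbor)
    ages = [v.ages[0] if v.ages else None for v in cleaned]
    if all(a is None for a in ages):
        return None
    n = len(ages)
    imputed = list(ages)
    for i in range(n):
        if imputed[i] is not None:
            continue
        prev_age = next((ages[j] for j in range(i - 1, -1, -1) if ages[j] is not None), None)
        next_age = next((ages[j] for j in range(i + 1, n) if ages[j] is not None), None)
        if prev_age is not None and next_age is not None:
            imputed[i] = round((prev_age + next_age) / 2.0, 1)
        else:
            imputed[i] = prev_age if prev_age is not None else next_age
    final = tuple(
        v if v.ages == (a,) else replace(v, ages=(a,)) for v, a in zip(cleaned, imputed)
    )
    return replace(record, visits=final)


def refine_cohort(raw: Cohort, chronic_codes: Optional[Set[str]] = None):
    """Apply the five refinement rules; returns (refined cohort, report).

    By default every vocabulary code is treated as chronic for the
    first-occurrence rule; pass ``chronic_codes`` to restrict it.
    """
    chronic = set(chronic_codes) if chronic_codes is not None else set(raw.vocabulary)
    kept = []
    n_no_anchor = n_no_sex = n_no_aged = 0
    for r in raw.records:
        if not r.has_code(raw.anchor_code):  # rule 1
            n_no_anchor += 1
            continue
        if r.sex is None:
            n_no_sex += 1
            continue
        refined = _refine_record(r, chronic)
        if refined is None:
            n_no_aged += 1
            continue
        kept.append(refined)
    report = DiscardReport(
        n_input=len(raw.records),
        n_output=len(kept),
        n_no_anchor=n_no_anchor,
        n_no_sex=n_no_sex,
        n_no_aged_visit=n_no_aged,
    )
    return raw.with_records(kept), report


def refine_for_prediction(refined: Cohort):
    """Prediction-task exclusions: non-ascending ages, endpoint before anchor."""
    kept = []
    n_non_asc = n_end_before = 0
    for r in refined.records:
        ages = [v.effective_age for v in r.visits if v.effective_age is not None]
        if any(b < a for a, b in zip(ages, ages[1:])):
            n_non_asc += 1
            continue
        end_age = r.first_age_of(refined.endpoint_code)
        anchor_age = r.first_age_of(refined.anchor_code)
        if end_age is not None and anchor_age is not None and end_age < anchor_age:
            n_end_before += 1
            continue
        kept.append(r)
    report = DiscardReport(
        n_input=len(refined.records),
        n_output=len(kept),
        n_non_ascending=n_non_asc,
        n_endpoint_before_anchor=n_end_before,
    )
    return refined.with_records(kept), report
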