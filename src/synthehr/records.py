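"""Core domain types for longitudinal diabetes EHR cohorts.

A patient record is a sex label plus an ordered sequence of visits, each visit
being an age (years) together with a *set* of diagnosis codes.  A cohort bundles
records with the diagnosis-code vocabulary and the two special codes: the
diabetes *anchor* (cohort inclusion criterion) and the chronic-kidney-disease
*endpoint* (the prediction label).

Cohorts serialize to JSON-lines, one record per line.  ``flatten`` produces the
one-row-per-patient tabular view (``PatientFeatureTable``) that every
column-wise metric downstream consumes.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from typing import Iterable, Iterator, Optional

import numpy as np
import pandas as pd

__all__ = [
    "Visit",
    "PatientRecord",
    "Cohort",
    "PatientFeatureTable",
    "CohortError",
    "CohortParseError",
    "read_cohort",
    "write_cohort",
    "flatten",
]

DEFAULT_ANCHOR = "DM"
DEFAULT_ENDPOINT = "CKD"

FEMALE = "female"
MALE = "male"


class CohortError(ValueError):
    """Validation failure on a cohort or record."""


class CohortParseError(CohortError):
    """Malformed serialized cohort; carries the offending line number."""

    def __init__(self, message: str, line: int):
        super().__init__(f"line {line}: {message}")
        self.line = line


@dataclass(frozen=True)
class Visit:
    """One visit: a set of diagnosis codes plus age label(s) in years.

    Well-formed visits carry exactly one age.  Raw generated visits may carry
    zero or several age labels (the refinement pipeline repairs both), so ages
    are stored as a tuple; ``age`` is the single age when unambiguous.
    """

    codes: frozenset
    ages: tuple = ()

    def __post_init__(self):
        if any(a < 0 for a in self.ages):
            raise CohortError(f"negative visit age in {self.ages}")

    @property
    def age(self) -> Optional[float]:
        return self.ages[0] if len(self.ages) == 1 else None

    @property
    def effective_age(self) -> Optional[float]:
        """Maximum age label, or None for an age-less visit."""
        return max(self.ages) if self.ages else None

    @staticmethod
    def make(age: float, codes: Iterable[str]) -> "Visit":
        return Visit(codes=frozenset(codes), ages=(round(float(age), 1),))


@dataclass(frozen=True)
class PatientRecord:
    id: str
    sex: Optional[str]  # "female" | "male" | None (missing)
    visits: tuple  # tuple[Visit, ...], canonical temporal order
    diagnosis_year: Optional[int] = None

    def codes(self) -> frozenset:
        out = set()
        for v in self.visits:
            out |= v.codes
        return frozenset(out)

    def has_code(self, code: str) -> bool:
        return any(code in v.codes for v in self.visits)

    def first_age_of(self, code: str) -> Optional[float]:
        """Age of the first (visit-order) aged visit containing ``code``."""
        for v in self.visits:
            if code in v.codes and v.effective_age is not None:
                return v.effective_age
        return None


@dataclass(frozen=True)
class Cohort:
    records: tuple  # tuple[PatientRecord, ...]
    vocabulary: tuple  # tuple[str, ...], ordered
    anchor_code: str = DEFAULT_ANCHOR
    endpoint_code: str = DEFAULT_ENDPOINT

    def __post_init__(self):
        ids = [r.id for r in self.records]
        if len(set(ids)) != len(ids):
            raise CohortError("duplicate record ids in cohort")
        vocab = set(self.vocabulary)
        for r in self.records:
            unknown = r.codes() - vocab
            if unknown:
                raise CohortError(
                    f"record {r.id} uses codes outside the vocabulary: {sorted(unknown)}"
                )

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[PatientRecord]:
        return iter(self.records)

    @property
    def comorbidity_codes(self) -> tuple:
        """Vocabulary minus the anchor code (the endpoint is kept: it is a
        regular column for fidelity metrics and the label source for TSTR)."""
        return tuple(c for c in self.vocabulary if c != self.anchor_code)

    def with_records(self, records) -> "Cohort":
        return replace(self, records=tuple(records))


# ---------------------------------------------------------------------------
# Serialization (JSON-lines; header line with vocabulary metadata)
# ---------------------------------------------------------------------------

def _visit_to_json(v: Visit) -> dict:
    d: dict = {"codes": sorted(v.codes)}
    if len(v.ages) == 1:
        d["age"] = v.ages[0]
    else:
        d["age"] = None
        d["ages"] = list(v.ages)
    return d


def _visit_from_json(d: dict) -> Visit:
    if "ages" in d and d.get("ages") is not None:
        ages = tuple(float(a) for a in d["ages"])
    elif d.get("age") is not None:
        ages = (float(d["age"]),)
    else:
        ages = ()
    return Visit(codes=frozenset(d.get("codes", [])), ages=ages)


def write_cohort(cohort: Cohort, path) -> None:
    with open(path, "w") as fh:
        header = {
            "_header": True,
            "vocabulary": list(cohort.vocabulary),
            "anchor_code": cohort.anchor_code,
            "endpoint_code": cohort.endpoint_code,
        }
        fh.write(json.dumps(header) + "\n")
        for r in cohort.records:
            row = {
                "id": r.id,
                "sex": r.sex,
                "visits": [_visit_to_json(v) for v in r.visits],
            }
            if r.diagnosis_year is not None:
                row["diagnosis_year"] = r.diagnosis_year
            fh.write(json.dumps(row) + "\n")


def read_cohort(path) -> Cohort:
    records = []
    vocabulary: list = []
    anchor, endpoint = DEFAULT_ANCHOR, DEFAULT_ENDPOINT
    seen_ids = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            try:
                obj = json.loads(line)
            except json.JSONDecodeError as exc:
                raise CohortParseError(f"invalid JSON ({exc.msg})", lineno) from exc
            if obj.get("_header"):
                vocabulary = list(obj.get("vocabulary", []))
                anchor = obj.get("anchor_code", anchor)
                endpoint = obj.get("endpoint_code", endpoint)
                continue
            if "id" not in obj:
                raise CohortParseError("record missing 'id'", lineno)
            if "visits" not in obj:
                raise CohortParseError("record missing 'visits'", lineno)
            if obj["id"] in seen_ids:
                raise CohortError(f"duplicate record id {obj['id']!r} at line {lineno}")
            seen_ids.add(obj["id"])
            try:
                visits = tuple(_visit_from_json(v) for v in obj["visits"])
            except (TypeError, KeyError, ValueError) as exc:
                raise CohortParseError(f"malformed visit list ({exc})", lineno) from exc
            records.append(
                PatientRecord(
                    id=str(obj["id"]),
                    sex=obj.get("sex"),
                    visits=visits,
                    diagnosis_year=obj.get("diagnosis_year"),
                )
            )
    observed = set()
    for r in records:
        observed |= r.codes()
    vocab = list(vocabulary) + sorted(observed - set(vocabulary))
    return Cohort(
        records=tuple(records),
        vocabulary=tuple(vocab),
        anchor_code=anchor,
        endpoint_code=endpoint,
    )


# ---------------------------------------------------------------------------
# Flat tabular view
# ---------------------------------------------------------------------------

CONTINUOUS = "continuous"
CATEGORICAL = "categorical"
BOOLEAN = "boolean"


@dataclass
class PatientFeatureTable:
    """One row per patient; the substrate for all column-wise metrics.

    Columns: ``sex`` (categorical), ``age_at_diabetes`` (continuous), per
    comorbidity code ``c`` a presence flag ``c`` (boolean) and the age at first
    diagnosis ``age_{c}`` (continuous, NaN when the flag is false), and
    ``visit_count`` (continuous).  ``schema`` tags every column.
    """

    frame: pd.DataFrame
    schema: dict = field(default_factory=dict)

    def __post_init__(self):
        missing = set(self.frame.columns) - set(self.schema)
        if missing:
            raise CohortError(f"schema does not cover columns: {sorted(missing)}")

    def __len__(self) -> int:
        return len(self.frame)

    def columns_of_type(self, kind: str) -> list:
        return [c for c in self.frame.columns if self.schema[c] == kind]

    @property
    def continuous_columns(self) -> list:
        return self.columns_of_type(CONTINUOUS)

    @property
    def discrete_columns(self) -> list:
        return [
            c
            for c in self.frame.columns
            if self.schema[c] in (CATEGORICAL, BOOLEAN)
        ]

    def to_csv(self, path, schema_path=None) -> None:
        self.frame.to_csv(path, index=False)
        if schema_path is not None:
            with open(schema_path, "w") as fh:
                json.dump(self.schema, fh, indent=1)


def flatten(cohort: Cohort, include_ages: bool = True) -> PatientFeatureTable:
    """Flatten a cohort into the per-patient feature table.

    First-occurrence rule: the age recorded for a code is the effective age of
    the first visit (in record order) that both contains the code and carries
    an age label; raw generated records may have age-less visits.
    """
    codes = cohort.comorbidity_codes
    rows = []
    for r in cohort.records:
        row: dict = {
            "sex": r.sex,
            "age_at_diabetes": r.first_age_of(cohort.anchor_code),
            "visit_count": len(r.visits),
        }
        present = r.codes()
        for c in codes:
            row[c] = c in present
            if include_ages:
                row[f"age_{c}"] = r.first_age_of(c) if c in present else None
        rows.append(row)
    columns = ["sex", "age_at_diabetes"]
    for c in codes:
        columns.append(c)
        if include_ages:
            columns.append(f"age_{c}")
    columns.append("visit_count")
    frame = pd.DataFrame(rows, columns=columns)
    frame["age_at_diabetes"] = frame["age_at_diabetes"].astype(float)
    if include_ages:
        for c in codes:
            frame[f"age_{c}"] = frame[f"age_{c}"].astype(float)
    schema = {"sex": CATEGORICAL, "age_at_diabetes": CONTINUOUS, "visit_count": CONTINUOUS}
    for c in codes:
        schema[c] = BOOLEAN
        if include_ages:
            schema[f"age_{c}"] = CONTINUOUS
    return PatientFeatureTable(frame=frame, schema=schema)


def cohorts_equal(a: Cohort, b: Cohort) -> bool:
    """Structural equality, tolerant of float round-trips through JSON."""
    if (
        tuple(a.vocabulary) != tuple(b.vocabulary)
        or a.anchor_code != b.anchor_code
        or a.endpoint_code != b.endpoint_code
        or len(a) != len(b)
    ):
        return False
    for ra, rb in zip(a.records, b.records):
        if (ra.id, ra.sex, ra.diagnosis_year) != (rb.id, rb.sex, rb.diagnosis_year):
            return False
        if len(ra.visits) != len(rb.visits):
            return False
        for va, vb in zip(ra.visits, rb.visits):
            if va.codes != vb.codes or len(va.ages) != len(vb.ages):
                return False
            if not np.allclose(va.ages, vb.ages):
                return False
    return True
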