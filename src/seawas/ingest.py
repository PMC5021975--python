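"""Flat-file EHR ingest: patients, diagnoses, vocabulary mapping, cohort filters.

The analysis operates on per-patient presence/absence of mapped diagnosis
codes. A patient is a *case* for a condition if the mapped code appears at
least once in their record; everyone else in the cohort is a control for
that condition. Patients therefore contribute to every condition they carry.

Readers accept RFC 4180 CSV (quoted fields, CRLF or LF). Only flat files are
supported — no database connectivity.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: columns every patients table must provide; anything else is treated as a
#: demographic attribute column.
RESERVED_PATIENT_COLUMNS = ("patient_id", "birth_year", "birth_month")


class MalformedRowsError(ValueError):
    """Raised after a full parse pass, listing every offending row by line number."""

    def __init__(self, path, rows):
        self.path = str(path)
        self.rows = list(rows)
        detail = "; ".join(f"line {line}: {why}" for line, why in self.rows)
        super().__init__(f"{self.path}: {detail}")


@dataclass(slots=True)
class PatientRecord:
    """One person: birth month/year, demographics, and their set of condition codes.

    ``birth_month`` is calendar-indexed, 1 = January through 12 = December.
    ``condition_codes`` has set semantics: a diagnosis recorded many times
    still counts once.
    """

    patient_id: str
    birth_year: int
    birth_month: int
    demographics: dict[str, str] = field(default_factory=dict)
    condition_codes: set[str] = field(default_factory=set)


@dataclass
class MappingLoss:
    """Tally of source codes dropped because the vocabulary mapping lacks them.

    Unmapped codes are a reported, not fatal, condition: downstream analysis
    is defined on the target vocabulary, so sources without a target are
    dropped and counted here rather than passed through.
    """

    n_codes_seen: int = 0
    n_codes_mapped: int = 0
    n_codes_dropped: int = 0
    dropped: Counter = field(default_factory=Counter)

    def summary(self) -> str:
        return (
            f"mapping loss: {self.n_codes_dropped}/{self.n_codes_seen} "
            f"source-code occurrences unmapped "
            f"({len(self.dropped)} distinct codes)"
        )


@dataclass
class CodeMapping:
    """Many-to-many source→target code mapping (e.g. ICD-9 → SNOMED-CT).

    A source code may map to several targets and several sources may share a
    target; exactly duplicated entries are collapsed.
    """

    entries: list[tuple[str, str, str, str]]

    def __post_init__(self) -> None:
        seen: set[tuple[str, str, str, str]] = set()
        deduped = []
        for entry in self.entries:
            entry = tuple(str(x) for x in entry)
            if len(entry) != 4:
                raise ValueError(f"mapping entry must have 4 fields, got {entry!r}")
            if entry not in seen:
                seen.add(entry)
                deduped.append(entry)
        self.entries = deduped
        by_source: dict[str, set[str]] = {}
        for source_code, _svocab, target_code, _tvocab in self.entries:
            by_source.setdefault(source_code, set()).add(target_code)
        self._by_source = {k: tuple(sorted(v)) for k, v in by_source.items()}

    @classmethod
    def from_csv(cls, path) -> "CodeMapping":
        """Load a mapping table with header
        ``source_code,source_vocabulary,target_code,target_vocabulary``."""
        df = pd.read_csv(path, dtype=str)
        required = ["source_code", "source_vocabulary", "target_code", "target_vocabulary"]
        missing = [c for c in required if c not in df.columns]
        if missing:
            raise ValueError(f"{path}: mapping file missing columns {missing}")
        return cls(entries=[tuple(row) for row in df[required].itertuples(index=False)])

    def targets(self, source_code: str) -> tuple[str, ...]:
        return self._by_source.get(source_code, ())


def apply_mapping(
    codes: set[str], mapping: CodeMapping, loss: MappingLoss | None = None
) -> set[str]:
    """Map a set of source codes to the union of their target codes.

    Source codes absent from the mapping are dropped; if a :class:`MappingLoss`
    is supplied the drops are tallied there. The result is independent of the
    iteration order of ``codes``.
    """
    mapped: set[str] = set()
    for code in codes:
        targets = mapping.targets(code)
        if loss is not None:
            loss.n_codes_seen += 1
        if targets:
            mapped.update(targets)
            if loss is not None:
                loss.n_codes_mapped += 1
        elif loss is not None:
            loss.n_codes_dropped += 1
            loss.dropped[code] += 1
    return mapped


@dataclass(frozen=True)
class CohortFilter:
    """Inclusion window on birth year (and, when recorded, treatment year).

    The birth-year window is inclusive at both ends. Treatment-year bounds are
    honoured only when patients carry a ``service_year`` demographic column;
    flat extracts without visit data simply ignore them.
    """

    birth_year_min: int
    birth_year_max: int
    treatment_year_min: int | None = None
    treatment_year_max: int | None = None

    def __post_init__(self) -> None:
        if self.birth_year_min > self.birth_year_max:
            raise ValueError("birth_year_min must be <= birth_year_max")
        if (
            self.treatment_year_min is not None
            and self.treatment_year_max is not None
            and self.treatment_year_min > self.treatment_year_max
        ):
            raise ValueError("treatment_year_min must be <= treatment_year_max")


def read_patients(
    patients_path,
    diagnoses_path,
    mapping: CodeMapping | None = None,
    loss: MappingLoss | None = None,
) -> list[PatientRecord]:
    """Read patients and diagnoses tables into :class:`PatientRecord` objects.

    One record per unique ``patient_id``; patients without diagnoses are kept
    with an empty code set. If ``mapping`` is given, diagnosis codes are mapped
    to the target vocabulary (unmapped codes dropped, tallied in ``loss``).

    Raises
    ------
    MalformedRowsError
        if any row has a non-integer or out-of-range birth month/year; all
        offending rows are collected and reported with their line numbers.
    ValueError
        if a ``patient_id`` recurs with conflicting birth fields.
    """
    pdf = pd.read_csv(patients_path, dtype=str)
    missing = [c for c in RESERVED_PATIENT_COLUMNS if c not in pdf.columns]
    if missing:
        raise ValueError(f"{patients_path}: patients file missing columns {missing}")

    years = pd.to_numeric(pdf["birth_year"], errors="coerce")
    months = pd.to_numeric(pdf["birth_month"], errors="coerce")
    bad_rows: list[tuple[int, str]] = []
    for i in range(len(pdf)):
        line = i + 2  # header is line 1
        y, m = years.iloc[i], months.iloc[i]
        if pd.isna(m) or m != int(m) or not (1 <= m <= 12):
            bad_rows.append((line, f"birth_month {pdf['birth_month'].iloc[i]!r} not in 1..12"))
        if pd.isna(y) or y != int(y) or not (1000 <= y <= 9999):
            bad_rows.append((line, f"birth_year {pdf['birth_year'].iloc[i]!r} not a 4-digit year"))
    if bad_rows:
        raise MalformedRowsError(patients_path, bad_rows)
    pdf = pdf.assign(birth_year=years.astype(int), birth_month=months.astype(int))

    dup_mask = pdf["patient_id"].duplicated(keep=False)
    if dup_mask.any():
        birth = pdf.loc[dup_mask].groupby("patient_id")[["birth_year", "birth_month"]].nunique()
        conflicting = birth[(birth > 1).any(axis=1)].index.tolist()
        if conflicting:
            raise ValueError(
                f"{patients_path}: duplicate patient_id with conflicting birth fields: "
                f"{conflicting}"
            )
        pdf = pdf.drop_duplicates(subset="patient_id", keep="first")

    demo_cols = [c for c in pdf.columns if c not in RESERVED_PATIENT_COLUMNS]

    ddf = pd.read_csv(diagnoses_path, dtype=str)
    for col in ("patient_id", "code"):
        if col not in ddf.columns:
            raise ValueError(f"{diagnoses_path}: diagnoses file missing column {col!r}")
    codes_by_patient: dict[str, set[str]] = {}
    known = set(pdf["patient_id"])
    n_orphan = 0
    for pid, code in zip(ddf["patient_id"], ddf["code"]):
        if pid not in known:
            n_orphan += 1
            continue
        codes_by_patient.setdefault(pid, set()).add(code)
    if n_orphan:
        logger.warning(
            "%s: %d diagnosis rows reference patients absent from %s; ignored",
            diagnoses_path, n_orphan, patients_path,
        )

    records = []
    for row in pdf.itertuples(index=False):
        pid = row.patient_id
        codes = codes_by_patient.get(pid, set())
        if mapping is not None:
            codes = apply_mapping(codes, mapping, loss)
        demographics = {c: getattr(row, c) for c in demo_cols}
        records.append(
            PatientRecord(
                patient_id=pid,
                birth_year=int(row.birth_year),
                birth_month=int(row.birth_month),
                demographics=demographics,
                condition_codes=codes,
            )
        )
    if loss is not None and loss.n_codes_dropped:
        logger.info(loss.summary())
    return records


def filter_cohort(patients: list[PatientRecord], f: CohortFilter) -> list[PatientRecord]:
    """Keep patients with birth year inside the inclusive window, preserving order.

    Treatment-year bounds apply only to patients carrying a ``service_year``
    demographic value; records without one are retained (the filter is
    idempotent either way).
    """
    out = []
    for p in patients:
        if not (f.birth_year_min <= p.birth_year <= f.birth_year_max):
            continue
        service = p.demographics.get("service_year")
        if service is not None and (
            f.treatment_year_min is not None or f.treatment_year_max is not None
        ):
            try:
                sy = int(service)
            except (TypeError, ValueError):
                sy = None
            if sy is not None:
                if f.treatment_year_min is not None and sy < f.treatment_year_min:
                    continue
                if f.treatment_year_max is not None and sy > f.treatment_year_max:
                    continue
        out.append(p)
    return out


@dataclass
class MonthlyCaseCounts:
    """Per-condition case counts by birth month, plus the cohort month totals.

    ``cases[code]`` is a length-12 integer vector (January first);
    ``totals[code]`` is its sum, i.e. the number of distinct patients carrying
    the code. ``population_by_month`` counts every cohort patient by birth
    month and sums to ``n_patients``.
    """

    cases: dict[str, np.ndarray]
    totals: dict[str, int]
    population_by_month: np.ndarray
    n_patients: int


def condition_case_counts(patients: list[PatientRecord]) -> MonthlyCaseCounts:
    """Tabulate, for every condition code, how many carriers were born each month."""
    population = np.zeros(12, dtype=np.int64)
    cases: dict[str, np.ndarray] = {}
    for p in patients:
        m = p.birth_month - 1
        population[m] += 1
        for code in p.condition_codes:
            vec = cases.get(code)
            if vec is None:
                vec = cases[code] = np.zeros(12, dtype=np.int64)
            vec[m] += 1
    totals = {code: int(vec.sum()) for code, vec in cases.items()}
    return MonthlyCaseCounts(
        cases=cases,
        totals=totals,
        population_by_month=population,
        n_patients=len(patients),
    )
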