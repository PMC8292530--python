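"""Cohort manifests: the slide/patient/site/outcome table behind every analysis.

A cohort manifest is one row per slide, carrying the slide id, patient id,
tissue-submitting site id, and any number of declared outcome columns
(categorical labels or continuous values, with missing cells allowed).
The manifest is the unit of I/O for site-heterogeneity testing and fold
construction.

CSV dialect: comma-separated, UTF-8, header row required, empty string means
missing.  Continuous values are written back with the shortest decimal
representation, so write -> read -> write is a fixpoint.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence, Union

import pandas as pd

__all__ = [
    "CATEGORICAL",
    "CONTINUOUS",
    "OutcomeColumn",
    "SlideRecord",
    "CohortManifest",
    "ManifestError",
    "read_manifest",
    "write_manifest",
]

CATEGORICAL = "categorical"
CONTINUOUS = "continuous"

#: In-memory marker for a missing outcome cell ("" on disk).
MISSING = None

OutcomeValue = Union[str, float, None]


class ManifestError(ValueError):
    """Malformed manifest file or invariant violation."""


@dataclass(frozen=True)
class OutcomeColumn:
    """Declaration of one outcome column: its name and kind."""

    name: str
    kind: str = CATEGORICAL

    def __post_init__(self) -> None:
        if self.kind not in (CATEGORICAL, CONTINUOUS):
            raise ManifestError(
                f"outcome column {self.name!r}: kind must be "
                f"{CATEGORICAL!r} or {CONTINUOUS!r}, got {self.kind!r}"
            )


@dataclass
class SlideRecord:
    """One slide: identifiers plus its outcome cells."""

    slide_id: str
    patient_id: str
    site_id: str
    outcomes: dict[str, OutcomeValue] = field(default_factory=dict)


@dataclass
class CohortManifest:
    """A multi-site cohort: slide records plus declared outcome columns.

    Invariants (checked on construction via :func:`validate`):

    * slide ids are unique,
    * every row has a non-empty patient id and site id,
    * a patient id maps to exactly one site id,
    * records reference only declared outcome columns.
    """

    records: list[SlideRecord]
    outcome_columns: list[OutcomeColumn]

    def __post_init__(self) -> None:
        self.validate()

    # -- invariants -------------------------------------------------------

    def validate(self) -> None:
        declared = {c.name for c in self.outcome_columns}
        seen_slides: set[str] = set()
        patient_site: dict[str, str] = {}
        for rec in self.records:
            if not rec.slide_id:
                raise ManifestError("empty slide id")
            if rec.slide_id in seen_slides:
                raise ManifestError(f"duplicate slide id {rec.slide_id!r}")
            seen_slides.add(rec.slide_id)
            if not rec.patient_id:
                raise ManifestError(f"slide {rec.slide_id!r}: empty patient id")
            if not rec.site_id:
                raise ManifestError(f"slide {rec.slide_id!r}: empty site id")
            prev = patient_site.setdefault(rec.patient_id, rec.site_id)
            if prev != rec.site_id:
                raise ManifestError(
                    f"patient {rec.patient_id!r} mapped to two sites: "
                    f"{prev!r} and {rec.site_id!r}"
                )
            extra = set(rec.outcomes) - declared
            if extra:
                raise ManifestError(
                    f"slide {rec.slide_id!r}: undeclared outcome columns {sorted(extra)}"
                )

    # -- views ------------------------------------------------------------

    @property
    def site_ids(self) -> list[str]:
        """Distinct site ids, in first-appearance order."""
        return list(dict.fromkeys(r.site_id for r in self.records))

    @property
    def patient_ids(self) -> list[str]:
        return list(dict.fromkeys(r.patient_id for r in self.records))

    def column(self, name: str) -> OutcomeColumn:
        for c in self.outcome_columns:
            if c.name == name:
                return c
        raise KeyError(name)

    def slides_per_site(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for r in self.records:
            counts[r.site_id] = counts.get(r.site_id, 0) + 1
        return counts

    def site_of_patient(self) -> dict[str, str]:
        return {r.patient_id: r.site_id for r in self.records}

    def patient_outcome(self, name: str) -> dict[str, OutcomeValue]:
        """Per-patient value for one outcome column.

        A patient's value is the first non-missing cell among their slides;
        conflicting non-missing values raise :class:`ManifestError`.
        """
        self.column(name)
        values: dict[str, OutcomeValue] = {}
        for r in self.records:
            v = r.outcomes.get(name, MISSING)
            if r.patient_id not in values:
                values[r.patient_id] = v
            elif v is not MISSING:
                prev = values[r.patient_id]
                if prev is MISSING:
                    values[r.patient_id] = v
                elif prev != v:
                    raise ManifestError(
                        f"patient {r.patient_id!r}: conflicting values for "
                        f"{name!r}: {prev!r} vs {v!r}"
                    )
        return values

    def missing_count(self, name: str) -> int:
        self.column(name)
        return sum(1 for r in self.records if r.outcomes.get(name, MISSING) is MISSING)

    def subset(self, keep: Iterable[str]) -> "CohortManifest":
        """New manifest containing only slides whose site id is in *keep*."""
        keep = set(keep)
        return CohortManifest(
            records=[r for r in self.records if r.site_id in keep],
            outcome_columns=list(self.outcome_columns),
        )

    def to_dataframe(self) -> pd.DataFrame:
        cols = ["slide_id", "patient_id", "site_id"] + [c.name for c in self.outcome_columns]
        rows = []
        for r in self.records:
            row = {"slide_id": r.slide_id, "patient_id": r.patient_id, "site_id": r.site_id}
            for c in self.outcome_columns:
                row[c.name] = r.outcomes.get(c.name, MISSING)
            rows.append(row)
        return pd.DataFrame(rows, columns=cols)

    def with_column(
        self, column: OutcomeColumn, values: Mapping[str, OutcomeValue]
    ) -> "CohortManifest":
        """New manifest with an extra outcome column keyed by patient id."""
        records = []
        for r in self.records:
            outcomes = dict(r.outcomes)
            outcomes[column.name] = values.get(r.patient_id, MISSING)
            records.append(SlideRecord(r.slide_id, r.patient_id, r.site_id, outcomes))
        return CohortManifest(records, list(self.outcome_columns) + [column])


def _parse_cell(raw: str, kind: str, path: str, line_no: int) -> OutcomeValue:
    if raw == "":
        return MISSING
    if kind == CONTINUOUS:
        try:
            return float(raw)
        except ValueError as exc:
            raise ManifestError(
                f"{path}:{line_no}: cannot parse {raw!r} as a number"
            ) from exc
    return raw


def read_manifest(
    path: Union[str, Path],
    schema: Union[Sequence[OutcomeColumn], Mapping[str, str]],
) -> CohortManifest:
    """Read a cohort manifest CSV.

    Parameters
    ----------
    path : path to a CSV with header ``slide_id,patient_id,site_id,...``.
    schema : outcome column declarations — either a sequence of
        :class:`OutcomeColumn` or a ``{name: kind}`` mapping.  Declared
        columns must be present in the header; undeclared extra columns are
        ignored.

    Raises
    ------
    ManifestError
        On malformed rows (named by line number) or invariant violations
        (e.g. a patient appearing under two sites).
    """
    path = Path(path)
    if isinstance(schema, Mapping):
        columns = [OutcomeColumn(n, k) for n, k in schema.items()]
    else:
        columns = list(schema)

    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh)
        try:
            header = next(reader)
        except StopIteration:
            raise ManifestError(f"{path}: empty file") from None
        required = ["slide_id", "patient_id", "site_id"] + [c.name for c in columns]
        missing_cols = [c for c in required if c not in header]
        if missing_cols:
            raise ManifestError(f"{path}: missing columns {missing_cols}")
        idx = {name: header.index(name) for name in required}

        records = []
        for line_no, row in enumerate(reader, start=2):
            if not row:
                continue
            if len(row) != len(header):
                raise ManifestError(
                    f"{path}:{line_no}: expected {len(header)} fields, got {len(row)}"
                )
            outcomes = {
                c.name: _parse_cell(row[idx[c.name]], c.kind, str(path), line_no)
                for c in columns
            }
            records.append(
                SlideRecord(
                    slide_id=row[idx["slide_id"]],
                    patient_id=row[idx["patient_id"]],
                    site_id=row[idx["site_id"]],
                    outcomes=outcomes,
                )
            )
    return CohortManifest(records, columns)


def _format_cell(value: OutcomeValue) -> str:
    if value is MISSING:
        return ""
    if isinstance(value, float):
        if math.isnan(value):
            return ""
        return repr(value) if value != int(value) else str(int(value))
    return str(value)


def write_manifest(manifest: CohortManifest, path: Union[str, Path]) -> None:
    """Write a manifest back to CSV (missing cells as empty strings)."""
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        header = ["slide_id", "patient_id", "site_id"] + [
            c.name for c in manifest.outcome_columns
        ]
        writer.writerow(header)
        for r in manifest.records:
            writer.writerow(
                [r.slide_id, r.patient_id, r.site_id]
                + [_format_cell(r.outcomes.get(c.name, MISSING)) for c in manifest.outcome_columns]
            )
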