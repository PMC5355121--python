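"""Study-level data model and tab-separated I/O.

A :class:`CohortStudy` holds what one cohort of a pharmacogenetic
case-control / dose study publishes: genotype counts (TT/CT/CC, T being the
variant allele of NUDT15 rs116855232) for the myelotoxicity and
no-myelotoxicity arms, and per-genotype summaries of the maintenance
thiopurine dose.  The packaged transcription of the source meta-analysis
table ships as a TSV fixture (see :func:`thiometa.fixtures.table1_fixture`).

The TSV dialect is UTF-8, tab-separated, one header row, empty string for an
absent value (never 0).  Studies that publish dose summaries only for the
combined T-carrier group use the ``T_CARRIER`` genotype label.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Mapping

import pandas as pd

__all__ = [
    "GenotypeCounts",
    "DoseSummary",
    "CohortStudy",
    "StudySet",
    "StudyParseError",
    "StudyValidationError",
    "read_studies",
    "write_studies",
    "GENOTYPE_LABELS",
    "TSV_COLUMNS",
]

GENOTYPE_LABELS = ("TT", "CT", "CC", "T_CARRIER")

ENDPOINT_MYELOTOXICITY = "myelotoxicity"
ENDPOINT_DOSE = "dose"
_ENDPOINTS = frozenset({ENDPOINT_MYELOTOXICITY, ENDPOINT_DOSE})


class StudyValidationError(ValueError):
    """A study or study set violates a structural invariant."""


class StudyParseError(ValueError):
    """A delimited input row could not be interpreted."""


@dataclass(frozen=True)
class GenotypeCounts:
    """Genotype counts for one arm: tt/ct/cc are individuals, not alleles."""

    tt: int
    ct: int
    cc: int

    def __post_init__(self) -> None:
        for name in ("tt", "ct", "cc"):
            v = getattr(self, name)
            if not isinstance(v, int) or isinstance(v, bool) or v < 0:
                raise StudyValidationError(
                    f"genotype count {name!r} must be a non-negative integer, got {v!r}"
                )

    def total(self) -> int:
        return self.tt + self.ct + self.cc

    def carriers(self) -> int:
        """Individuals with at least one variant allele (TT or CT)."""
        return self.tt + self.ct

    def variant_alleles(self) -> int:
        return 2 * self.tt + self.ct

    def reference_alleles(self) -> int:
        return 2 * self.cc + self.ct


@dataclass(frozen=True)
class DoseSummary:
    """Summary of daily AZA-equivalent dose (mg/m^2) for one genotype group.

    ``norm_mean``/``norm_sd`` are dimensionless (dose divided by the CC-group
    mean of the same study) and are filled only by
    :func:`thiometa.dose.normalize_against_reference`.
    """

    mean: float
    sd: float | None = None
    n: int | None = None
    norm_mean: float | None = None
    norm_sd: float | None = None

    def __post_init__(self) -> None:
        if not (self.mean > 0) or not math.isfinite(self.mean):
            raise StudyValidationError(f"dose mean must be > 0, got {self.mean!r}")
        if self.sd is not None and (self.sd < 0 or not math.isfinite(self.sd)):
            raise StudyValidationError(f"dose sd must be >= 0, got {self.sd!r}")
        if self.n is not None and (not isinstance(self.n, int) or self.n < 0):
            raise StudyValidationError(f"dose n must be a non-negative int, got {self.n!r}")


@dataclass(frozen=True)
class CohortStudy:
    study_id: str
    disease: str  # "IBD" or "ALL"
    endpoints: frozenset[str]
    author: str = ""
    year: int | None = None
    ethnicity: str = ""
    case_counts: GenotypeCounts | None = None
    control_counts: GenotypeCounts | None = None
    dose: Mapping[str, DoseSummary] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.study_id:
            raise StudyValidationError("study_id must be non-empty")
        if self.disease not in ("IBD", "ALL"):
            raise StudyValidationError(
                f"{self.study_id}: disease must be IBD or ALL, got {self.disease!r}"
            )
        bad = set(self.endpoints) - _ENDPOINTS
        if bad or not self.endpoints:
            raise StudyValidationError(
                f"{self.study_id}: endpoints must be a non-empty subset of "
                f"{sorted(_ENDPOINTS)}, got {sorted(self.endpoints)}"
            )
        for label in self.dose:
            if label not in GENOTYPE_LABELS:
                raise StudyValidationError(
                    f"{self.study_id}: unknown dose genotype label {label!r}"
                )
        if ENDPOINT_MYELOTOXICITY in self.endpoints:
            if self.case_counts is None or self.control_counts is None:
                raise StudyValidationError(
                    f"{self.study_id}: myelotoxicity endpoint requires both "
                    "case_counts and control_counts"
                )
        if ENDPOINT_DOSE in self.endpoints:
            if "CC" not in self.dose:
                raise StudyValidationError(
                    f"{self.study_id}: dose endpoint requires a CC (reference) "
                    "dose summary"
                )

    @property
    def has_both_arms(self) -> bool:
        return self.case_counts is not None and self.control_counts is not None


@dataclass(frozen=True)
class StudySet:
    studies: tuple[CohortStudy, ...]
    provenance: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "studies", tuple(self.studies))
        seen: set[str] = set()
        for s in self.studies:
            if s.study_id in seen:
                raise StudyValidationError(f"duplicate study_id {s.study_id!r}")
            seen.add(s.study_id)

    def __len__(self) -> int:
        return len(self.studies)

    def __iter__(self) -> Iterator[CohortStudy]:
        return iter(self.studies)

    def __getitem__(self, study_id: str) -> CohortStudy:
        for s in self.studies:
            if s.study_id == study_id:
                return s
        raise KeyError(study_id)

    def subset(self, endpoint: str) -> "StudySet":
        """Studies participating in the given endpoint, in original order."""
        if endpoint not in _ENDPOINTS:
            raise ValueError(f"unknown endpoint {endpoint!r}")
        return StudySet(
            tuple(s for s in self.studies if endpoint in s.endpoints),
            provenance=self.provenance,
        )

    def myelotoxicity_subset(self) -> "StudySet":
        return self.subset(ENDPOINT_MYELOTOXICITY)

    def dose_subset(self) -> "StudySet":
        return self.subset(ENDPOINT_DOSE)


# ---------------------------------------------------------------------------
# TSV I/O

TSV_COLUMNS = [
    "study_id", "author", "year", "ethnicity", "disease", "endpoints",
    "tt_case", "ct_case", "cc_case", "tt_ctrl", "ct_ctrl", "cc_ctrl",
]
for _g in ("tt", "ct", "cc", "tcarrier"):
    TSV_COLUMNS += [f"dose_{_g}_n", f"dose_{_g}_mean", f"dose_{_g}_sd"]

_DOSE_LABEL_BY_COL = {"tt": "TT", "ct": "CT", "cc": "CC", "tcarrier": "T_CARRIER"}


def _cell_int(row: Mapping[str, object], col: str, line: int) -> int | None:
    raw = row.get(col)
    if raw is None or (isinstance(raw, float) and math.isnan(raw)) or raw == "":
        return None
    try:
        v = int(str(raw).strip())
    except ValueError:
        raise StudyParseError(f"line {line}: column {col!r}: not an integer: {raw!r}")
    return v


def _cell_float(row: Mapping[str, object], col: str, line: int) -> float | None:
    raw = row.get(col)
    if raw is None or (isinstance(raw, float) and math.isnan(raw)) or raw == "":
        return None
    try:
        return float(str(raw).strip())
    except ValueError:
        raise StudyParseError(f"line {line}: column {col!r}: not a number: {raw!r}")


def _counts_from_row(row, arm: str, line: int) -> GenotypeCounts | None:
    vals = [_cell_int(row, f"{g}_{arm}", line) for g in ("tt", "ct", "cc")]
    if all(v is None for v in vals):
        return None
    if any(v is None for v in vals):
        raise StudyParseError(
            f"line {line}: partial genotype counts for arm {arm!r}; "
            "give all of tt/ct/cc or none"
        )
    return GenotypeCounts(*vals)


def read_studies(path: str | Path, provenance: str | None = None) -> StudySet:
    """Read a study table from the packaged TSV dialect.

    Absent numeric cells (empty strings) map to absent values, never zero.
    Raises :class:`StudyParseError` naming the offending line, or
    :class:`StudyValidationError` for contract violations (e.g. negative
    counts, duplicate ids).
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    required = {"study_id", "disease", "endpoints"}
    missing = required - set(df.columns)
    if missing:
        raise StudyParseError(f"{path}: missing required columns {sorted(missing)}")

    studies: list[CohortStudy] = []
    for i, row in enumerate(df.to_dict("records")):
        line = i + 2  # 1-based, after the header row
        endpoints = frozenset(
            e.strip() for e in str(row.get("endpoints", "")).split(",") if e.strip()
        )
        dose: dict[str, DoseSummary] = {}
        for col, label in _DOSE_LABEL_BY_COL.items():
            mean = _cell_float(row, f"dose_{col}_mean", line)
            if mean is None:
                continue
            dose[label] = DoseSummary(
                mean=mean,
                sd=_cell_float(row, f"dose_{col}_sd", line),
                n=_cell_int(row, f"dose_{col}_n", line),
            )
        try:
            study = CohortStudy(
                study_id=str(row["study_id"]).strip(),
                author=str(row.get("author", "") or ""),
                year=_cell_int(row, "year", line),
                ethnicity=str(row.get("ethnicity", "") or ""),
                disease=str(row["disease"]).strip(),
                endpoints=endpoints,
                case_counts=_counts_from_row(row, "case", line),
                control_counts=_counts_from_row(row, "ctrl", line),
                dose=dose,
            )
        except StudyValidationError as exc:
            raise StudyValidationError(f"line {line}: {exc}") from None
        studies.append(study)
    return StudySet(
        tuple(studies),
        provenance=provenance if provenance is not None else f"read from {path}",
    )


def _fmt(v) -> str:
    if v is None:
        return ""
    if isinstance(v, float):
        return repr(v)
    return str(v)


def write_studies(study_set: StudySet | Iterable[CohortStudy], path: str | Path) -> Path:
    """Write a StudySet in the TSV dialect read by :func:`read_studies`.

    Round-trips: ``read_studies(write_studies(s, p))`` equals ``s`` field by
    field (provenance excepted, which records the source file).
    """
    if not isinstance(study_set, StudySet):
        study_set = StudySet(tuple(study_set))
    path = Path(path)
    rows = []
    for s in study_set:
        row = {c: "" for c in TSV_COLUMNS}
        row.update(
            study_id=s.study_id, author=s.author, year=_fmt(s.year),
            ethnicity=s.ethnicity, disease=s.disease,
            endpoints=",".join(sorted(s.endpoints)),
        )
        for arm, counts in (("case", s.case_counts), ("ctrl", s.control_counts)):
            if counts is not None:
                row[f"tt_{arm}"] = str(counts.tt)
                row[f"ct_{arm}"] = str(counts.ct)
                row[f"cc_{arm}"] = str(counts.cc)
        for col, label in _DOSE_LABEL_BY_COL.items():
            d = s.dose.get(label)
            if d is not None:
                row[f"dose_{col}_n"] = _fmt(d.n)
                row[f"dose_{col}_mean"] = _fmt(d.mean)
                row[f"dose_{col}_sd"] = _fmt(d.sd)
        rows.append(row)
    pd.DataFrame(rows, columns=TSV_COLUMNS).to_csv(path, sep="\t", index=False)
    return path


def normalized_copy(study: CohortStudy, dose: Mapping[str, DoseSummary]) -> CohortStudy:
    """Return the study with its dose map replaced (used by the pipeline)."""
    return replace(study, dose=dict(dose))
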