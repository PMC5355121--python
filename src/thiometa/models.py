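"""Genetic-model contingency tables and carrier diagnostics.

Each genetic model collapses per-arm TT/CT/CC genotype counts into a 2x2
exposure-by-outcome table:

* ``ALLELE``     — T allele vs C allele; each individual contributes two
  independent allele observations (2*TT+CT exposed, 2*CC+CT unexposed).
* ``DOMINANT``   — carriers (TT+CT) vs CC.
* ``RECESSIVE``  — TT vs CT+CC (equivalently, TT vs the rest).
* ``CT_VS_REST`` — CT vs TT+CC; the heterozygote-vs-rest contrast that, with
  the recessive contrast, forms the per-genotype comparison reported by the
  source analysis.
* ``CT_VS_CC``   — CT vs CC, restricted to CT and CC individuals only.
* ``TT_VS_CC``   — TT vs CC, restricted to TT and CC individuals only.
"""

from __future__ import annotations

import statistics
from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Sequence

import pandas as pd

from .studies import CohortStudy, GenotypeCounts, StudySet

__all__ = [
    "ModelKind",
    "TwoByTwo",
    "DiagnosticSummary",
    "GenotypeRates",
    "build_contrast",
    "contrasts_for",
    "carrier_diagnostics",
    "genotype_event_rates",
    "tables_to_frame",
]


class ModelKind(str, Enum):
    ALLELE = "allele"
    DOMINANT = "dominant"
    RECESSIVE = "recessive"
    CT_VS_REST = "ct_vs_rest"
    CT_VS_CC = "ct_vs_cc"
    TT_VS_CC = "tt_vs_cc"


@dataclass(frozen=True)
class TwoByTwo:
    """One study's exposure-by-outcome table (a=case exposed, etc.)."""

    study_id: str
    case_exposed: float
    case_unexposed: float
    control_exposed: float
    control_unexposed: float

    def __post_init__(self) -> None:
        for v in self.cells():
            if v < 0:
                raise ValueError(f"{self.study_id}: negative cell in 2x2 table")

    def cells(self) -> tuple[float, float, float, float]:
        return (
            self.case_exposed,
            self.case_unexposed,
            self.control_exposed,
            self.control_unexposed,
        )

    @property
    def n(self) -> float:
        return sum(self.cells())

    def has_zero_cell(self) -> bool:
        return any(v == 0 for v in self.cells())

    def is_double_zero(self) -> bool:
        """Zero exposed (or zero unexposed) in both arms: OR carries no
        information and the study is excluded from pooling."""
        return (self.case_exposed == 0 and self.control_exposed == 0) or (
            self.case_unexposed == 0 and self.control_unexposed == 0
        )

    def corrected(self) -> "TwoByTwo":
        """Continuity correction: add 0.5 to all four cells if any is zero."""
        if not self.has_zero_cell():
            return self
        a, b, c, d = self.cells()
        return TwoByTwo(self.study_id, a + 0.5, b + 0.5, c + 0.5, d + 0.5)

    def swapped_arms(self) -> "TwoByTwo":
        return TwoByTwo(
            self.study_id,
            self.control_exposed,
            self.control_unexposed,
            self.case_exposed,
            self.case_unexposed,
        )


def _arm_split(counts: GenotypeCounts, model: ModelKind) -> tuple[int, int] | None:
    """(exposed, unexposed) for one arm; None drops the arm's excluded
    genotypes (restricted contrasts only restrict, they cannot fail)."""
    if model is ModelKind.ALLELE:
        return counts.variant_alleles(), counts.reference_alleles()
    if model is ModelKind.DOMINANT:
        return counts.carriers(), counts.cc
    if model is ModelKind.RECESSIVE:
        return counts.tt, counts.ct + counts.cc
    if model is ModelKind.CT_VS_REST:
        return counts.ct, counts.tt + counts.cc
    if model is ModelKind.CT_VS_CC:
        return counts.ct, counts.cc
    if model is ModelKind.TT_VS_CC:
        return counts.tt, counts.cc
    raise ValueError(f"unknown model {model!r}")


def build_contrast(
    case: GenotypeCounts,
    control: GenotypeCounts,
    model: ModelKind,
    study_id: str = "",
) -> TwoByTwo:
    """Collapse genotype counts of both arms into the model's 2x2 table.

    Degenerate tables (e.g. an exposure stratum empty in both arms) are
    returned as-is; exclusion is the pooling stage's decision.
    """
    ca = _arm_split(case, model)
    co = _arm_split(control, model)
    return TwoByTwo(study_id, ca[0], ca[1], co[0], co[1])


def contrasts_for(study_set: StudySet, model: ModelKind) -> list[TwoByTwo]:
    """Per-study 2x2 tables over the myelotoxicity subset (both arms)."""
    out = []
    for s in study_set.myelotoxicity_subset():
        out.append(build_contrast(s.case_counts, s.control_counts, model, s.study_id))
    return out


def tables_to_frame(tables: Iterable[TwoByTwo], model: ModelKind | None = None) -> pd.DataFrame:
    """Serializable audit table (study_id, a, b, c, d, model)."""
    rows = [
        {
            "study_id": t.study_id,
            "a": t.case_exposed,
            "b": t.case_unexposed,
            "c": t.control_exposed,
            "d": t.control_unexposed,
            "model": model.value if model is not None else "",
        }
        for t in tables
    ]
    return pd.DataFrame(rows, columns=["study_id", "a", "b", "c", "d", "model"])


@dataclass(frozen=True)
class DiagnosticSummary:
    """Carrier status (TT or CT) as a classifier for myelotoxicity."""

    tp: int  # carriers among cases
    fn: int  # non-carriers among cases
    tn: int  # non-carriers among controls
    fp: int  # carriers among controls

    @property
    def sensitivity(self) -> float:
        return self.tp / (self.tp + self.fn)

    @property
    def specificity(self) -> float:
        return self.tn / (self.tn + self.fp)


def carrier_diagnostics(study_set: StudySet) -> DiagnosticSummary:
    """Aggregate carrier counts over the myelotoxicity subset."""
    subset = study_set.myelotoxicity_subset()
    if len(subset) == 0:
        raise ValueError("no myelotoxicity studies with both arms")
    tp = fn = tn = fp = 0
    for s in subset:
        tp += s.case_counts.carriers()
        fn += s.case_counts.cc
        tn += s.control_counts.cc
        fp += s.control_counts.carriers()
    return DiagnosticSummary(tp=tp, fn=fn, tn=tn, fp=fp)


@dataclass(frozen=True)
class GenotypeRates:
    """Pooled per-genotype event rates and the spread of per-study CT rates.

    The pooled rate for genotype g is (cases with g)/(cases+controls with g)
    over the myelotoxicity subset; a genotype absent everywhere has rate None.
    """

    pooled: dict[str, float | None]
    ct_by_study: dict[str, float | None]
    ct_min: float | None
    ct_max: float | None
    ct_median: float | None


def genotype_event_rates(study_set: StudySet) -> GenotypeRates:
    subset = study_set.myelotoxicity_subset()
    if len(subset) == 0:
        raise ValueError("no myelotoxicity studies with both arms")
    pooled: dict[str, float | None] = {}
    for g in ("TT", "CT", "CC"):
        attr = g.lower()
        cases = sum(getattr(s.case_counts, attr) for s in subset)
        total = cases + sum(getattr(s.control_counts, attr) for s in subset)
        pooled[g] = cases / total if total > 0 else None
    ct_by_study: dict[str, float | None] = {}
    for s in subset:
        denom = s.case_counts.ct + s.control_counts.ct
        ct_by_study[s.study_id] = s.case_counts.ct / denom if denom > 0 else None
    observed = sorted(v for v in ct_by_study.values() if v is not None)
    return GenotypeRates(
        pooled=pooled,
        ct_by_study=ct_by_study,
        ct_min=observed[0] if observed else None,
        ct_max=observed[-1] if observed else None,
        ct_median=statistics.median(observed) if observed else None,
    )
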