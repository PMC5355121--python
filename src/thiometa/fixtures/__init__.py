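"""Packaged transcription of the source meta-analysis study table."""

from __future__ import annotations

from importlib import resources

from ..studies import StudySet, read_studies

__all__ = ["table1_fixture"]


def table1_fixture() -> StudySet:
    """The packaged study table: 11 articles contributing 20 cohort records.

    The myelotoxicity subset has exactly 7 case-control studies (602 cases,
    1150 controls); the dose subset has 13 cohorts.  Articles contributing to
    both endpoints appear as two records (``X`` and ``X-dose``); dose-only
    records carry per-genotype dose summaries whose ``n`` is the number of
    genotyped patients with dose data (case and control arms combined where
    both were published).
    """
    with resources.as_file(
        resources.files(__package__) / "table1.tsv"
    ) as p:
        return read_studies(p, provenance="packaged transcription of the source study table")
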