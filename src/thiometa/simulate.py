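"""Seeded generators for meta-analysis cohorts, dose studies and eQTL panels.

Every generator is a pure function of its configuration (seed included),
using NumPy's default_rng (PCG64), so outputs are bitwise reproducible for a
given NumPy version.  Defaults emulate the study ensemble the pipeline was
built around: 7 case-control cohorts with the fixture's arm sizes, a control
variant-allele frequency of 0.1 (East-Asian-like for NUDT15 rs116855232), an
allele-level odds ratio of 8, and a 447-sample expression panel with one
causal variant.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .eqtl import ExpressionVector, GenotypePanel, SnpRecord
from .studies import CohortStudy, DoseSummary, GenotypeCounts, StudySet

__all__ = [
    "MetaSimConfig",
    "EqtlSimConfig",
    "FIXTURE_CASE_SIZES",
    "FIXTURE_CONTROL_SIZES",
    "simulate_meta_cohorts",
    "simulate_dose_study",
    "simulate_dose_cohorts",
    "simulate_eqtl_panel",
]

# arm sizes of the 7 packaged myelotoxicity case-control cohorts
FIXTURE_CASE_SIZES = (346, 34, 45, 65, 38, 28, 46)
FIXTURE_CONTROL_SIZES = (632, 101, 116, 188, 54, 54, 5)


@dataclass(frozen=True)
class MetaSimConfig:
    k: int = 7
    n_case: int | Sequence[int] = FIXTURE_CASE_SIZES
    n_control: int | Sequence[int] = FIXTURE_CONTROL_SIZES
    maf: float = 0.1  # control variant-allele frequency
    true_or: float = 8.0  # allele-level odds ratio
    tau: float = 0.0  # between-study SD of the log OR
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.maf < 1):
            raise ValueError("maf must be in (0, 1)")
        if not (self.true_or > 0) or self.tau < 0 or self.k < 1:
            raise ValueError("invalid simulation config")
        for name in ("n_case", "n_control"):
            v = getattr(self, name)
            if not isinstance(v, int):
                if len(v) != self.k:
                    raise ValueError(f"{name} must be an int or a length-k sequence")


def _sizes(v: int | Sequence[int], k: int) -> list[int]:
    return [v] * k if isinstance(v, int) else list(v)


def _hwe_draw(rng: np.random.Generator, n: int, p_variant: float) -> GenotypeCounts:
    probs = [p_variant**2, 2 * p_variant * (1 - p_variant), (1 - p_variant) ** 2]
    tt, ct, cc = rng.multinomial(n, probs)
    return GenotypeCounts(int(tt), int(ct), int(cc))


def simulate_meta_cohorts(cfg: MetaSimConfig) -> StudySet:
    """Simulate k case-control cohorts under a true allele-level OR.

    Per study, a log OR is drawn from Normal(log true_or, tau^2); control
    genotypes follow Hardy-Weinberg at ``maf``, and case genotypes follow
    Hardy-Weinberg at the allele frequency obtained by tilting the control
    odds by the study OR (logit shift), matching the allele-model definition
    of the odds ratio used in pooling.
    """
    rng = np.random.default_rng(cfg.seed)
    ncs = _sizes(cfg.n_case, cfg.k)
    nts = _sizes(cfg.n_control, cfg.k)
    studies = []
    for i in range(cfg.k):
        or_i = float(np.exp(rng.normal(np.log(cfg.true_or), cfg.tau)))
        odds_ctrl = cfg.maf / (1 - cfg.maf)
        p_case = odds_ctrl * or_i / (1 + odds_ctrl * or_i)
        studies.append(
            CohortStudy(
                study_id=f"sim{i + 1:02d}",
                disease="IBD",
                endpoints=frozenset({"myelotoxicity"}),
                case_counts=_hwe_draw(rng, ncs[i], p_case),
                control_counts=_hwe_draw(rng, nts[i], cfg.maf),
            )
        )
    return StudySet(tuple(studies), provenance=f"simulated (seed={cfg.seed})")


def simulate_dose_study(
    true_reduction: float,
    n_by_genotype: dict[str, int] | None = None,
    sd: float = 0.35,
    seed: int = 0,
    nominal_cc: float = 2.5,
    study_id: str = "simdose",
    disease: str = "IBD",
) -> CohortStudy:
    """Simulate one dose cohort and summarize it per genotype.

    CC patients dose around ``nominal_cc`` (mg/m^2 AZA-equivalent, an
    IBD-scale default); carriers (CT and TT) around
    (1 - true_reduction) * nominal_cc.  ``sd`` is the patient-level SD as a
    fraction of the nominal dose.  Doses are truncated at a small positive
    floor so summaries remain valid.
    """
    if not (0 <= true_reduction < 1):
        raise ValueError("true_reduction must be in [0, 1)")
    if n_by_genotype is None:
        n_by_genotype = {"CC": 100, "CT": 20, "TT": 2}
    if any(n <= 0 for n in n_by_genotype.values()):
        raise ValueError("group sizes must be positive")
    rng = np.random.default_rng(seed)
    dose: dict[str, DoseSummary] = {}
    for label, n in n_by_genotype.items():
        mean = nominal_cc if label == "CC" else nominal_cc * (1 - true_reduction)
        x = np.maximum(rng.normal(mean, sd * nominal_cc, size=n), 1e-3)
        dose[label] = DoseSummary(
            mean=float(x.mean()),
            sd=float(x.std(ddof=1)) if n > 1 else None,
            n=int(n),
        )
    return CohortStudy(
        study_id=study_id, disease=disease, endpoints=frozenset({"dose"}), dose=dose
    )


def simulate_dose_cohorts(
    k: int,
    true_reduction: float,
    n_by_genotype: dict[str, int] | None = None,
    sd: float = 0.35,
    seed: int = 0,
) -> StudySet:
    """k independent dose cohorts sharing one true carrier dose reduction."""
    child = np.random.SeedSequence(seed).spawn(k)
    studies = tuple(
        simulate_dose_study(
            true_reduction,
            n_by_genotype,
            sd,
            seed=int(child[i].generate_state(1)[0] % (2**31)),
            study_id=f"simdose{i + 1:02d}",
        )
        for i in range(k)
    )
    return StudySet(studies, provenance=f"simulated dose cohorts (seed={seed})")


@dataclass(frozen=True)
class EqtlSimConfig:
    n_samples: int = 447
    n_snps: int = 100
    maf_range: tuple[float, float] = (0.05, 0.5)
    causal_beta: float = -0.5
    noise_sd: float = 1.0
    causal_index: int | None = None  # default: the middle variant
    chrom: str = "13"
    window: tuple[int, int] = (48582000, 48622000)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_samples < 3 or self.n_snps < 1:
            raise ValueError("need n_samples >= 3 and n_snps >= 1")
        if not (self.noise_sd > 0):
            raise ValueError("noise_sd must be positive")
        lo, hi = self.maf_range
        if not (0 < lo <= hi < 1):
            raise ValueError("invalid maf_range")


def simulate_eqtl_panel(cfg: EqtlSimConfig) -> tuple[GenotypePanel, ExpressionVector]:
    """Hardy-Weinberg genotypes plus expression driven by one causal variant.

    expression = causal_beta * causal dosage + Normal(0, noise_sd^2); with
    causal_beta = 0 every variant is null.
    """
    rng = np.random.default_rng(cfg.seed)
    mafs = rng.uniform(*cfg.maf_range, size=cfg.n_snps)
    geno = rng.binomial(2, mafs[None, :], size=(cfg.n_samples, cfg.n_snps)).astype(float)
    causal = cfg.causal_index if cfg.causal_index is not None else cfg.n_snps // 2
    expr = cfg.causal_beta * geno[:, causal] + rng.normal(0, cfg.noise_sd, cfg.n_samples)
    positions = np.sort(
        rng.choice(np.arange(cfg.window[0], cfg.window[1]), cfg.n_snps, replace=False)
    )
    snps = tuple(
        SnpRecord(
            "rs_causal" if j == causal else f"rs_sim{j:04d}", cfg.chrom, int(positions[j])
        )
        for j in range(cfg.n_snps)
    )
    samples = tuple(f"S{i:04d}" for i in range(cfg.n_samples))
    return GenotypePanel(samples, snps, geno), ExpressionVector(samples, expr)
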