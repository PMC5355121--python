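"""Dose unit conversion, reference normalization, carrier-group combination.

Published maintenance doses mix drugs (azathioprine vs 6-mercaptopurine) and
units; the pipeline converts 6-MP to AZA-equivalents with a fixed factor
(default 2.08), converts body-weight dosing to body-surface-area dosing via
the Meeh-Rubner allometric formula, and finally normalizes each study's
per-genotype mean dose against its own CC (wild-type) group so cohorts are
comparable on a dimensionless scale where CC == 1.  Because normalization is
within-study, the drug conversion factor cancels and mixed-drug cohorts
remain comparable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import yaml

from .studies import DoseSummary, StudyValidationError

__all__ = [
    "DoseConversionConfig",
    "load_config",
    "to_aza_equivalent",
    "meeh_rubner_bsa",
    "normalize_against_reference",
    "combine_carrier_groups",
    "pooled_mean_sd",
    "CARRIER_POLICIES",
]

CARRIER_POLICIES = ("drop_sd_less", "zero_sd")


@dataclass(frozen=True)
class DoseConversionConfig:
    """mp_to_aza_factor: 6-MP -> AZA-equivalent multiplier.

    meeh_k: Meeh-Rubner constant k in A = k * W^(2/3) / 1e4 with W in grams
    and A in m^2; 10.1 is the common human value.
    """

    mp_to_aza_factor: float = 2.08
    meeh_k: float = 10.1

    def __post_init__(self) -> None:
        if not (self.mp_to_aza_factor > 0 and self.meeh_k > 0):
            raise ValueError("conversion constants must be positive")


def load_config(path: str | Path) -> DoseConversionConfig:
    """Read a YAML (or flat key: value) config file; unknown keys rejected."""
    data = yaml.safe_load(Path(path).read_text()) or {}
    known = {"mp_to_aza_factor", "meeh_k"}
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    return DoseConversionConfig(**{k: float(v) for k, v in data.items()})


_DRUG_ALIASES = {
    "AZA": "AZA", "AZATHIOPRINE": "AZA",
    "6MP": "6MP", "6-MP": "6MP", "MP": "6MP", "MERCAPTOPURINE": "6MP",
}


def to_aza_equivalent(
    dose: float, drug: str, cfg: DoseConversionConfig = DoseConversionConfig()
) -> float:
    """Convert a dose of the given drug to its AZA-equivalent (same units)."""
    if dose < 0:
        raise ValueError("dose must be >= 0")
    canonical = _DRUG_ALIASES.get(drug.strip().upper())
    if canonical is None:
        raise ValueError(f"unknown drug label {drug!r}")
    return dose if canonical == "AZA" else dose * cfg.mp_to_aza_factor


def meeh_rubner_bsa(
    weight_kg: float, cfg: DoseConversionConfig = DoseConversionConfig()
) -> float:
    """Body surface area (m^2) from weight via A = k * (1000*W_kg)^(2/3) / 1e4."""
    if not (weight_kg > 0):
        raise ValueError("weight must be positive")
    return cfg.meeh_k * (1000.0 * weight_kg) ** (2.0 / 3.0) / 1e4


def normalize_against_reference(
    dose_by_genotype: Mapping[str, DoseSummary],
) -> dict[str, DoseSummary]:
    """Fill norm_mean/norm_sd by dividing every group by the CC mean.

    CC's norm_mean is exactly 1.  Groups without an sd keep norm_sd absent.
    The operation is scale-invariant: rescaling all means and sds by c > 0
    leaves the normalized values unchanged.
    """
    cc = dose_by_genotype.get("CC")
    if cc is None:
        raise StudyValidationError("missing CC reference dose summary")
    ref = cc.mean
    out: dict[str, DoseSummary] = {}
    for label, d in dose_by_genotype.items():
        out[label] = DoseSummary(
            mean=d.mean,
            sd=d.sd,
            n=d.n,
            norm_mean=1.0 if label == "CC" else d.mean / ref,
            norm_sd=None if d.sd is None else d.sd / ref,
        )
    return out


def pooled_mean_sd(
    n1: int, m1: float, s1: float, n2: int, m2: float, s2: float
) -> tuple[int, float, float]:
    """Exact summary of the concatenation of two summarized samples.

    Combined variance uses the within+between decomposition
    [(n1-1)s1^2 + (n2-1)s2^2 + n1*n2*(m1-m2)^2/N] / (N-1), which equals the
    sample variance of the pooled raw data when s1, s2 are sample SDs.
    """
    n = n1 + n2
    if n < 2:
        raise ValueError("combined group must have at least 2 observations")
    mean = (n1 * m1 + n2 * m2) / n
    var = ((n1 - 1) * s1**2 + (n2 - 1) * s2**2 + n1 * n2 * (m1 - m2) ** 2 / n) / (n - 1)
    return n, mean, math.sqrt(max(var, 0.0))


def combine_carrier_groups(
    ct: DoseSummary | None,
    tt: DoseSummary | None,
    policy: str = "drop_sd_less",
) -> DoseSummary:
    """Combine CT and TT dose summaries into one T-carrier summary.

    ``policy`` governs TT groups published without an SD (typically a single
    patient): ``drop_sd_less`` (default) ignores them and returns the CT
    summary; ``zero_sd`` folds them in via the combination formula with the
    missing SD taken as 0.  Combination is applied to raw mean/sd and, when
    both groups are normalized, to norm_mean/norm_sd as well.
    """
    if policy not in CARRIER_POLICIES:
        raise ValueError(f"unknown carrier policy {policy!r}")
    if ct is None and tt is None:
        raise ValueError("both carrier groups absent")
    if ct is None:
        return tt
    if tt is None or tt.n is None:
        return ct
    if tt.sd is None and (policy == "drop_sd_less" or ct.n is None):
        return ct
    if ct.n is None or ct.sd is None:
        return ct

    s2 = tt.sd if tt.sd is not None else 0.0
    n, mean, sd = pooled_mean_sd(ct.n, ct.mean, ct.sd, tt.n, tt.mean, s2)
    norm_mean = norm_sd = None
    if ct.norm_mean is not None and tt.norm_mean is not None and ct.norm_sd is not None:
        ns2 = tt.norm_sd if tt.norm_sd is not None else 0.0
        _, norm_mean, norm_sd = pooled_mean_sd(
            ct.n, ct.norm_mean, ct.norm_sd, tt.n, tt.norm_mean, ns2
        )
    return DoseSummary(mean=mean, sd=sd, n=n, norm_mean=norm_mean, norm_sd=norm_sd)


def carrier_summary(
    dose_by_genotype: Mapping[str, DoseSummary], policy: str = "drop_sd_less"
) -> DoseSummary | None:
    """The T-carrier dose group of one study: the published T_CARRIER row if
    present, else the CT/TT combination under ``policy``."""
    if "T_CARRIER" in dose_by_genotype:
        return dose_by_genotype["T_CARRIER"]
    ct = dose_by_genotype.get("CT")
    tt = dose_by_genotype.get("TT")
    if ct is None and tt is None:
        return None
    return combine_carrier_groups(ct, tt, policy=policy)
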