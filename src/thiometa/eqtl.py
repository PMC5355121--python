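"""Cis-eQTL scan: additive-dosage linear regression over a genomic window.

Genotypes are coded additively (0/1/2 copies of the non-reference allele;
indels count like SNVs), expression is a single normalized gene-level value
per sample.  Rare variants (fewer than ``min_carriers`` individuals with at
least one variant allele) are excluded before regression, and each retained
variant is tested by ordinary least squares of expression on dosage with an
intercept (slope t-test, n-2 df).  Missing dosages drop the sample for that
variant only (pairwise deletion).  Raw p-values are reported; a
Benjamini-Hochberg column is optional.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "SnpRecord",
    "GenotypePanel",
    "ExpressionVector",
    "EqtlResult",
    "ConstantDosageError",
    "read_dosage_matrix",
    "read_vcf_panel",
    "read_expression",
    "align",
    "filter_snps",
    "regress",
    "scan",
    "regional_table",
]


class ConstantDosageError(ValueError):
    """Dosage has no variation among complete pairs; slope undefined."""


@dataclass(frozen=True)
class SnpRecord:
    id: str
    chrom: str
    pos: int  # 1-based


@dataclass(frozen=True)
class GenotypePanel:
    """samples x variants dosage matrix; np.nan marks a missing call."""

    sample_ids: tuple[str, ...]
    snps: tuple[SnpRecord, ...]
    dosage: np.ndarray

    def __post_init__(self) -> None:
        d = np.asarray(self.dosage, dtype=float)
        object.__setattr__(self, "dosage", d)
        if d.shape != (len(self.sample_ids), len(self.snps)):
            raise ValueError(
                f"dosage shape {d.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.snps)} variants"
            )
        valid = d[~np.isnan(d)]
        if valid.size and not np.isin(valid, (0.0, 1.0, 2.0)).all():
            raise ValueError("dosages must be 0, 1, 2 or missing")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_snps(self) -> int:
        return len(self.snps)

    def carrier_counts(self) -> np.ndarray:
        """Individuals with dosage >= 1 per variant (missing not counted)."""
        with np.errstate(invalid="ignore"):
            return np.nansum(self.dosage >= 1, axis=0).astype(int)


@dataclass(frozen=True)
class ExpressionVector:
    sample_ids: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        if v.shape != (len(self.sample_ids),):
            raise ValueError("values must align with sample_ids")
        if not np.isfinite(v).all():
            raise ValueError("expression values must be finite")


@dataclass(frozen=True)
class EqtlResult:
    snp_id: str
    n: int
    beta: float
    se: float
    t: float
    p: float

    @property
    def neg_log10_p(self) -> float:
        return -math.log10(self.p)


# ---------------------------------------------------------------------------
# readers

def read_dosage_matrix(path: str | Path) -> GenotypePanel:
    """Delimited samples x variants matrix, cells 0/1/2 or NA.

    The first column holds sample ids; the header row holds variant ids in
    ``id:chrom:pos`` or plain-id form (position 0 when not encoded).
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    snps = []
    for col in df.columns:
        parts = str(col).split(":")
        if len(parts) == 3:
            snps.append(SnpRecord(parts[0], parts[1], int(parts[2])))
        else:
            snps.append(SnpRecord(str(col), "", 0))
    return GenotypePanel(
        tuple(str(i) for i in df.index), tuple(snps), df.to_numpy(dtype=float)
    )


def write_dosage_matrix(panel: GenotypePanel, path: str | Path) -> Path:
    cols = [f"{s.id}:{s.chrom}:{s.pos}" for s in panel.snps]
    df = pd.DataFrame(panel.dosage, index=list(panel.sample_ids), columns=cols)
    df.to_csv(path, sep="\t", na_rep="NA")
    return Path(path)


def read_vcf_panel(path: str | Path) -> GenotypePanel:
    """Read dosages from a VCF's GT field (any non-reference allele counts)."""
    from cyvcf2 import VCF  # optional dependency

    vcf = VCF(str(path))
    samples = tuple(vcf.samples)
    snps, cols = [], []
    for var in vcf:
        vid = var.ID or f"{var.CHROM}:{var.POS}"
        snps.append(SnpRecord(vid, str(var.CHROM), int(var.POS)))
        # gt_types: 0=hom-ref, 1=het, 3=hom-alt, 2=unknown
        gt = np.asarray(var.gt_types, dtype=float)
        col = np.where(gt == 0, 0.0, np.where(gt == 1, 1.0, np.where(gt == 3, 2.0, np.nan)))
        cols.append(col)
    dosage = np.column_stack(cols) if cols else np.empty((len(samples), 0))
    return GenotypePanel(samples, tuple(snps), dosage)


def read_expression(path: str | Path) -> ExpressionVector:
    """Two-column delimited file: sample_id <tab> value (no header required)."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    if df.shape[1] != 2:
        raise ValueError("expression file must have exactly two columns")
    return ExpressionVector(
        tuple(str(s) for s in df.iloc[:, 0]), df.iloc[:, 1].to_numpy(dtype=float)
    )


def align(
    panel: GenotypePanel, expression: ExpressionVector
) -> tuple[GenotypePanel, ExpressionVector]:
    """Intersect samples (panel order) so rows pair up."""
    expr_idx = {s: i for i, s in enumerate(expression.sample_ids)}
    keep = [i for i, s in enumerate(panel.sample_ids) if s in expr_idx]
    if not keep:
        raise ValueError("no overlapping samples")
    ids = tuple(panel.sample_ids[i] for i in keep)
    return (
        GenotypePanel(ids, panel.snps, panel.dosage[keep, :]),
        ExpressionVector(ids, expression.values[[expr_idx[s] for s in ids]]),
    )


# ---------------------------------------------------------------------------
# analysis

def filter_snps(panel: GenotypePanel, min_carriers: int = 3) -> GenotypePanel:
    """Drop variants carried by fewer than ``min_carriers`` individuals."""
    keep = panel.carrier_counts() >= min_carriers
    return GenotypePanel(
        panel.sample_ids,
        tuple(s for s, k in zip(panel.snps, keep) if k),
        panel.dosage[:, keep],
    )


def regress(expression: np.ndarray, dosage: np.ndarray, snp_id: str = "") -> EqtlResult:
    """OLS of expression on one variant's dosage with intercept.

    Complete pairs only; raises :class:`ConstantDosageError` when fewer than
    3 pairs remain or the dosage does not vary.
    """
    expression = np.asarray(expression, dtype=float)
    dosage = np.asarray(dosage, dtype=float)
    ok = ~np.isnan(dosage) & ~np.isnan(expression)
    x, y = dosage[ok], expression[ok]
    if len(x) < 3 or np.ptp(x) == 0:
        raise ConstantDosageError(snp_id or "variant")
    fit = stats.linregress(x, y)
    n = len(x)
    beta = float(fit.slope)
    se = float(fit.stderr)
    if se == 0:  # perfect fit: report t=inf, smallest representable p
        t = math.inf if beta != 0 else 0.0
        p = float(2 * stats.t.sf(abs(t), n - 2)) if math.isfinite(t) else 0.0
        p = max(p, np.finfo(float).tiny)
        return EqtlResult(snp_id, n, beta, se, t, p)
    t = beta / se
    p = float(2 * stats.t.sf(abs(t), n - 2))
    return EqtlResult(snp_id, n, beta, se, t, max(p, np.finfo(float).tiny))


def _scan_stats(dosage: np.ndarray, y: np.ndarray):
    """Vectorized per-variant OLS with pairwise deletion.

    Returns (n, beta, se, t, p) arrays; variants with constant dosage or
    fewer than 3 complete pairs come back with n set and the rest NaN.
    """
    miss = np.isnan(dosage)
    x = np.where(miss, 0.0, dosage)
    yv = y[:, None] * ~miss
    n = (~miss).sum(axis=0).astype(float)
    sx = x.sum(axis=0)
    sy = yv.sum(axis=0)
    sxx = (x * x).sum(axis=0)
    syy = (yv * yv).sum(axis=0)
    sxy = (x * yv).sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        Sxx = sxx - sx * sx / n
        Syy = syy - sy * sy / n
        Sxy = sxy - sx * sy / n
        beta = Sxy / Sxx
        resid_ss = np.maximum(Syy - beta * Sxy, 0.0)
        sigma2 = resid_ss / (n - 2)
        se = np.sqrt(sigma2 / Sxx)
        t = beta / se
        p = 2 * stats.t.sf(np.abs(t), n - 2)
    bad = (n < 3) | ~(Sxx > 0)
    for arr in (beta, se, t, p):
        arr[bad] = np.nan
    p = np.maximum(p, np.finfo(float).tiny)
    return n.astype(int), beta, se, t, p


def scan(
    panel: GenotypePanel,
    expression: ExpressionVector,
    bh_column: bool = False,
) -> pd.DataFrame:
    """Regress expression on every variant; rows sorted by ascending p.

    Variants with undefined slopes are retained with a ``skipped`` flag and
    NaN statistics, so the output is always a permutation of the input panel.
    """
    if panel.n_snps == 0:
        raise ValueError("empty panel")
    if panel.sample_ids != expression.sample_ids:
        panel, expression = align(panel, expression)
    n, beta, se, t, p = _scan_stats(panel.dosage, expression.values)
    df = pd.DataFrame(
        {
            "snp_id": [s.id for s in panel.snps],
            "chrom": [s.chrom for s in panel.snps],
            "pos": [s.pos for s in panel.snps],
            "n": n,
            "beta": beta,
            "se": se,
            "t": t,
            "p": p,
            "skipped": np.isnan(beta),
        }
    )
    df["neg_log10_p"] = -np.log10(df["p"])
    if bh_column:
        tested = df.loc[~df["skipped"], "p"]
        m = len(tested)
        order = tested.sort_values().index
        q = (tested[order] * m / np.arange(1, m + 1)).iloc[::-1].cummin().iloc[::-1]
        df.loc[order, "p_bh"] = np.minimum(q, 1.0)
    return df.sort_values("p", na_position="last", kind="mergesort").reset_index(drop=True)


def regional_table(scan_result: pd.DataFrame) -> pd.DataFrame:
    """Position-ordered (chrom, pos, snp_id, p, neg_log10_p) for plotting."""
    cols = ["chrom", "pos", "snp_id", "p", "neg_log10_p"]
    return (
        scan_result.loc[~scan_result["skipped"], cols]
        .sort_values("pos", kind="mergesort")
        .reset_index(drop=True)
    )
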