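"""Fixed- and random-effects pooling with heterogeneity.

Dichotomous outcomes are pooled as odds ratios, either by Mantel-Haenszel
(stratum-weighted, the default for 2x2 data) with the
Robins-Breslow-Greenland variance for the log pooled OR, or by
inverse-variance weighting of per-study log ORs.  Continuous outcomes
(normalized dose mean differences) are pooled by inverse variance, with
DerSimonian-Laird moment estimation of the between-study variance tau^2 for
random effects.  Heterogeneity is summarized by Cochran's Q around the
IV-fixed pooled estimate, its chi-square p-value (df = k-1), and
I^2 = max(0, (Q - df)/Q * 100).

Zero cells: any study 2x2 containing a zero has 0.5 added to all four cells
(applied consistently in the MH sums and the per-study log ORs, the
convention of the classic meta-analysis software for dichotomous data).  A
study with zero exposed — or zero unexposed — in both arms carries no
information about the odds ratio and is excluded with a reason.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .models import TwoByTwo
from .studies import DoseSummary

__all__ = [
    "EffectEstimate",
    "HeterogeneityResult",
    "PooledResult",
    "log_odds_ratio",
    "mh_pooled_or",
    "iv_fixed",
    "dl_random",
    "heterogeneity",
    "select_model",
    "mean_difference",
    "forest_frame",
]

_Z95 = stats.norm.ppf(0.975)  # 1.959964...


@dataclass(frozen=True)
class EffectEstimate:
    """One study's effect (log OR or mean difference) with its SE."""

    study_id: str
    effect: float
    se: float
    excluded: bool = False
    reason: str | None = None

    def __post_init__(self) -> None:
        if not self.excluded and not (self.se > 0):
            raise ValueError(f"{self.study_id}: se must be > 0 for an included effect")


@dataclass(frozen=True)
class HeterogeneityResult:
    Q: float
    df: int
    p: float
    i2: float  # percent, floored at 0
    tau2: float

    def __post_init__(self) -> None:
        if self.tau2 < 0 or not (0 <= self.i2 <= 100):
            raise ValueError("invalid heterogeneity result")


@dataclass(frozen=True)
class PooledResult:
    method: str  # MH_FIXED | IV_FIXED | DL_RANDOM
    estimate: float  # OR on the ratio scale, or MD
    ci_low: float
    ci_high: float
    z: float
    p: float
    k: int
    het: HeterogeneityResult | None
    weights: dict[str, float] | None = None  # percent weights per study
    excluded: tuple[EffectEstimate, ...] = ()
    log_scale: bool = False  # estimate was exponentiated from a log effect


def _included(effects: Iterable[EffectEstimate]) -> tuple[list[EffectEstimate], list[EffectEstimate]]:
    inc, exc = [], []
    for e in effects:
        (exc if e.excluded else inc).append(e)
    return inc, exc


def log_odds_ratio(table: TwoByTwo) -> EffectEstimate:
    """Per-study log OR and SE on continuity-corrected cells.

    Double-zero tables (no exposed, or no unexposed, in either arm) are
    returned flagged as excluded rather than raising.
    """
    if table.is_double_zero():
        return EffectEstimate(
            table.study_id, math.nan, math.nan, excluded=True,
            reason="no informative stratum (zero margin in both arms)",
        )
    a, b, c, d = table.corrected().cells()
    return EffectEstimate(
        table.study_id,
        math.log(a * d / (b * c)),
        math.sqrt(1 / a + 1 / b + 1 / c + 1 / d),
    )


def _wrap_pooled(
    method: str,
    est_log_or_raw: float,
    se: float,
    k: int,
    het: HeterogeneityResult | None,
    weights: dict[str, float] | None,
    excluded: Sequence[EffectEstimate],
    exponentiate: bool,
) -> PooledResult:
    z = est_log_or_raw / se
    p = 2 * stats.norm.sf(abs(z))
    lo = est_log_or_raw - _Z95 * se
    hi = est_log_or_raw + _Z95 * se
    if exponentiate:
        est, lo, hi = math.exp(est_log_or_raw), math.exp(lo), math.exp(hi)
    else:
        est = est_log_or_raw
    return PooledResult(
        method=method, estimate=est, ci_low=lo, ci_high=hi, z=z, p=p, k=k,
        het=het, weights=weights, excluded=tuple(excluded), log_scale=exponentiate,
    )


def mh_pooled_or(tables: Sequence[TwoByTwo]) -> PooledResult:
    """Mantel-Haenszel fixed-effect pooled OR over per-study 2x2 tables.

    SE of the log pooled OR by Robins-Breslow-Greenland.  Heterogeneity is
    computed from the per-study log ORs with inverse-variance weights around
    the IV-fixed pooled estimate (standard practice when reporting Q/I^2
    alongside an MH pooled OR).
    """
    effects = [log_odds_ratio(t) for t in tables]
    used = [t.corrected() for t in tables if not t.is_double_zero()]
    _, excluded = _included(effects)
    if not used:
        raise ValueError("all tables excluded from MH pooling")

    R = S = 0.0
    sPR = sPSQR = sQS = 0.0
    mh_weight: dict[str, float] = {}
    for t in used:
        a, b, c, d = t.cells()
        n = t.n
        r_i = a * d / n
        s_i = b * c / n
        p_i = (a + d) / n
        R += r_i
        S += s_i
        sPR += p_i * r_i
        sPSQR += p_i * s_i + (1 - p_i) * r_i
        sQS += (1 - p_i) * s_i
        mh_weight[t.study_id] = s_i
    log_or = math.log(R / S)
    se = math.sqrt(sPR / (2 * R * R) + sPSQR / (2 * R * S) + sQS / (2 * S * S))
    total_w = sum(mh_weight.values())
    weights = {sid: 100.0 * w / total_w for sid, w in mh_weight.items()}
    het = heterogeneity([e for e in effects if not e.excluded]) if len(used) >= 2 else None
    return _wrap_pooled("MH_FIXED", log_or, se, len(used), het, weights, excluded, True)


def _iv_core(effects: Sequence[EffectEstimate], tau2: float = 0.0):
    th = np.array([e.effect for e in effects])
    w = 1.0 / (np.array([e.se for e in effects]) ** 2 + tau2)
    est = float((w * th).sum() / w.sum())
    se = float(1.0 / math.sqrt(w.sum()))
    weights = {
        e.study_id: 100.0 * float(wi) / float(w.sum()) for e, wi in zip(effects, w)
    }
    return est, se, weights


def heterogeneity(effects: Sequence[EffectEstimate]) -> HeterogeneityResult:
    """Cochran's Q around the IV-fixed estimate; I^2 floored at 0; DL tau^2."""
    inc, _ = _included(effects)
    k = len(inc)
    if k < 2:
        raise ValueError("heterogeneity requires at least 2 included effects")
    th = np.array([e.effect for e in inc])
    w = 1.0 / np.array([e.se for e in inc]) ** 2
    est = (w * th).sum() / w.sum()
    Q = float((w * (th - est) ** 2).sum())
    df = k - 1
    p = float(stats.chi2.sf(Q, df))
    i2 = max(0.0, (Q - df) / Q * 100.0) if Q > 0 else 0.0
    C = float(w.sum() - (w**2).sum() / w.sum())
    tau2 = max(0.0, (Q - df) / C) if C > 0 else 0.0
    return HeterogeneityResult(Q=Q, df=df, p=p, i2=i2, tau2=tau2)


def iv_fixed(
    effects: Sequence[EffectEstimate], exponentiate: bool = False
) -> PooledResult:
    """Inverse-variance fixed-effect pooling (weights 1/se^2)."""
    inc, exc = _included(effects)
    if not inc:
        raise ValueError("no included effects")
    est, se, weights = _iv_core(inc)
    het = heterogeneity(inc) if len(inc) >= 2 else None
    return _wrap_pooled("IV_FIXED", est, se, len(inc), het, weights, exc, exponentiate)


def dl_random(
    effects: Sequence[EffectEstimate], exponentiate: bool = False
) -> PooledResult:
    """DerSimonian-Laird random-effects pooling.

    tau^2 = max(0, (Q - df)/C) with C = sum(w) - sum(w^2)/sum(w) on
    inverse-variance weights; random weights are 1/(se^2 + tau^2).  When
    Q <= df the estimator reduces exactly to the IV fixed-effect result.
    """
    inc, exc = _included(effects)
    if not inc:
        raise ValueError("no included effects")
    if len(inc) == 1:
        est, se, weights = _iv_core(inc)
        return _wrap_pooled("DL_RANDOM", est, se, 1, None, weights, exc, exponentiate)
    het = heterogeneity(inc)
    est, se, weights = _iv_core(inc, tau2=het.tau2)
    return _wrap_pooled("DL_RANDOM", est, se, len(inc), het, weights, exc, exponentiate)


def select_model(het: HeterogeneityResult) -> str:
    """Model-choice rule: FIXED iff I^2 < 50% and p > 0.1, else RANDOM.

    Boundary combinations (e.g. I^2 above 50% with non-significant p) fall to
    RANDOM, the conservative default.
    """
    return "FIXED" if (het.i2 < 50.0 and het.p > 0.1) else "RANDOM"


def mean_difference(
    g1: DoseSummary, g2: DoseSummary, study_id: str = ""
) -> EffectEstimate:
    """Unstandardized mean difference g1 - g2 on the normalized-dose scale.

    Requires n >= 2, a normalized mean, and a normalized sd in both groups;
    otherwise the study is returned flagged excluded with the reason.
    """
    for name, g in (("group1", g1), ("group2", g2)):
        if g.norm_mean is None:
            return EffectEstimate(study_id, math.nan, math.nan, True,
                                  f"{name} not normalized")
        if g.n is None or g.n < 2 or g.norm_sd is None:
            return EffectEstimate(study_id, math.nan, math.nan, True,
                                  f"{name} lacks n >= 2 with sd")
    effect = g1.norm_mean - g2.norm_mean
    se = math.sqrt(g1.norm_sd**2 / g1.n + g2.norm_sd**2 / g2.n)
    if se == 0:
        return EffectEstimate(study_id, math.nan, math.nan, True, "zero variance")
    return EffectEstimate(study_id, effect, se)


def forest_frame(
    effects: Sequence[EffectEstimate], pooled: PooledResult
) -> pd.DataFrame:
    """Forest-plot table: per-study rows plus a pooled row.

    Effects and CIs are reported on the pooled result's scale (ratio scale
    when the pooled estimate was exponentiated).
    """
    rows = []
    weights = pooled.weights or {}
    for e in effects:
        if e.excluded:
            rows.append({"study_id": e.study_id, "effect": math.nan,
                         "ci_low": math.nan, "ci_high": math.nan,
                         "weight_percent": 0.0, "note": e.reason or "excluded"})
            continue
        lo, hi = e.effect - _Z95 * e.se, e.effect + _Z95 * e.se
        eff = e.effect
        if pooled.log_scale:
            eff, lo, hi = math.exp(eff), math.exp(lo), math.exp(hi)
        rows.append({"study_id": e.study_id, "effect": eff, "ci_low": lo,
                     "ci_high": hi, "weight_percent": weights.get(e.study_id, math.nan),
                     "note": ""})
    rows.append({"study_id": f"POOLED ({pooled.method})", "effect": pooled.estimate,
                 "ci_low": pooled.ci_low, "ci_high": pooled.ci_high,
                 "weight_percent": 100.0, "note": ""})
    return pd.DataFrame(rows, columns=["study_id", "effect", "ci_low", "ci_high",
                                       "weight_percent", "note"])
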