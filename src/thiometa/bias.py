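"""Publication-bias tests and leave-one-out sensitivity analysis.

Egger's test is the classic regression of the standardized effect
(theta_i / se_i) on precision (1/se_i) by ordinary least squares; the
intercept measures funnel asymmetry and is tested with t on k-2 df.

Begg's (Begg-Mazumdar) test rank-correlates variance-adjusted standardized
deviates with the per-study variances: deviates are
(theta_i - theta_fixed) / sqrt(v_i - 1/sum(1/v_j)), correlated with v_i by
Kendall's tau-b, with the tie-corrected large-sample normal approximation
(an exact permutation p-value is available for small k).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .meta import EffectEstimate, PooledResult, iv_fixed

__all__ = [
    "BiasTestResult",
    "LeaveOneOutResult",
    "LeaveOneOutSummary",
    "eggers_test",
    "beggs_test",
    "leave_one_out",
    "funnel_data",
]

_Z95 = stats.norm.ppf(0.975)


@dataclass(frozen=True)
class BiasTestResult:
    method: str  # EGGER | BEGG
    statistic: float  # Egger intercept, or Kendall tau-b
    se_or_z: float  # intercept SE (Egger) or normal z (Begg)
    p: float


def _clean(effects: Sequence[EffectEstimate], k_min: int) -> list[EffectEstimate]:
    inc = [e for e in effects if not e.excluded]
    if len(inc) < k_min:
        raise ValueError(f"need at least {k_min} included effects, got {len(inc)}")
    return inc


def eggers_test(effects: Sequence[EffectEstimate]) -> BiasTestResult:
    inc = _clean(effects, 3)
    th = np.array([e.effect for e in inc])
    se = np.array([e.se for e in inc])
    y = th / se
    x = sm.add_constant(1.0 / se)
    fit = sm.OLS(y, x).fit()
    intercept = float(fit.params[0])
    se_int = float(fit.bse[0])
    t = intercept / se_int
    p = 2 * float(stats.t.sf(abs(t), len(inc) - 2))
    return BiasTestResult("EGGER", intercept, se_int, p)


def _tau_b(x: np.ndarray, y: np.ndarray) -> float:
    return float(stats.kendalltau(x, y, method="asymptotic").statistic)


def beggs_test(
    effects: Sequence[EffectEstimate], method: str = "asymptotic"
) -> BiasTestResult:
    """Begg-Mazumdar rank correlation test.

    ``method='exact'`` enumerates all permutations of the variances (k <= 8)
    and reports the two-sided fraction with |tau| at least as extreme.
    """
    inc = _clean(effects, 3)
    th = np.array([e.effect for e in inc])
    v = np.array([e.se for e in inc]) ** 2
    w = 1.0 / v
    pooled = float((w * th).sum() / w.sum())
    vstar = v - 1.0 / w.sum()
    # vstar is positive whenever k >= 2 and weights are finite
    deviates = (th - pooled) / np.sqrt(vstar)

    res = stats.kendalltau(deviates, v, method="asymptotic")
    tau = float(res.statistic)
    if method == "asymptotic":
        p = float(res.pvalue)  # tie-corrected normal approximation on S
        # recover the z statistic implied by the two-sided p
        z = float(stats.norm.isf(min(max(p / 2, 1e-300), 1.0)))
        return BiasTestResult("BEGG", tau, math.copysign(z, tau), p)
    if method == "exact":
        k = len(inc)
        if k > 8:
            raise ValueError("exact permutation limited to k <= 8")
        count = total = 0
        for perm in itertools.permutations(v):
            t_perm = _tau_b(deviates, np.array(perm))
            count += abs(t_perm) >= abs(tau) - 1e-12
            total += 1
        return BiasTestResult("BEGG", tau, math.nan, count / total)
    raise ValueError(f"unknown method {method!r}")


@dataclass(frozen=True)
class LeaveOneOutResult:
    omitted_study_id: str
    pooled: PooledResult


@dataclass(frozen=True)
class LeaveOneOutSummary:
    results: tuple[LeaveOneOutResult, ...]
    min_estimate: float
    max_estimate: float


def leave_one_out(
    items: Sequence, pool: Callable[[Sequence], PooledResult]
) -> LeaveOneOutSummary:
    """Re-pool k times, omitting one study each; items are whatever ``pool``
    accepts (2x2 tables for MH, effect estimates for IV/DL)."""
    if len(items) < 2:
        raise ValueError("leave-one-out requires at least 2 studies")
    results = []
    for i, omitted in enumerate(items):
        rest = [x for j, x in enumerate(items) if j != i]
        results.append(
            LeaveOneOutResult(getattr(omitted, "study_id", str(i)), pool(rest))
        )
    ests = [r.pooled.estimate for r in results]
    return LeaveOneOutSummary(tuple(results), min(ests), max(ests))


def funnel_data(
    effects: Sequence[EffectEstimate], pooled: PooledResult, n_guide: int = 50
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Plot-ready funnel coordinates.

    Returns (points, guides): per-study (effect, se) points on the pooling
    scale (log OR for ratio outcomes), and the pseudo-95% triangle
    theta_hat +/- 1.96*se evaluated on an se grid from 0 (the apex) to the
    largest observed se.
    """
    inc = [e for e in effects if not e.excluded]
    if not inc:
        raise ValueError("no included effects")
    center = math.log(pooled.estimate) if pooled.log_scale else pooled.estimate
    points = pd.DataFrame(
        {"study_id": [e.study_id for e in inc],
         "effect": [e.effect for e in inc],
         "se": [e.se for e in inc]}
    )
    se_grid = np.linspace(0.0, max(e.se for e in inc), n_guide)
    guides = pd.DataFrame(
        {"se": se_grid,
         "lower": center - _Z95 * se_grid,
         "upper": center + _Z95 * se_grid}
    )
    return points, guides
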