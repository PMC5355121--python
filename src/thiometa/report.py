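"""Report assembly: the two meta-analyses and the carrier diagnostics.

Each ``run_*`` function takes a :class:`~thiometa.studies.StudySet`, performs
the full pipeline for one analysis, optionally writes TSV/JSON artifacts to
an output directory, and returns a plain-dict summary (numbers at full
precision; rounding is a display concern).
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Sequence

from . import bias as bias_mod
from .dose import carrier_summary, normalize_against_reference
from .meta import (
    EffectEstimate,
    PooledResult,
    dl_random,
    forest_frame,
    iv_fixed,
    log_odds_ratio,
    mean_difference,
    mh_pooled_or,
    select_model,
)
from .models import (
    ModelKind,
    carrier_diagnostics,
    contrasts_for,
    genotype_event_rates,
    tables_to_frame,
)
from .studies import StudySet

__all__ = [
    "dose_effects",
    "pool_myelotoxicity",
    "run_myelotoxicity",
    "run_dose",
    "run_diagnostics",
]


def _het_dict(het) -> dict | None:
    return None if het is None else dataclasses.asdict(het)


def _pooled_dict(p: PooledResult) -> dict:
    return {
        "method": p.method,
        "estimate": p.estimate,
        "ci_low": p.ci_low,
        "ci_high": p.ci_high,
        "z": p.z,
        "p": p.p,
        "k": p.k,
        "heterogeneity": _het_dict(p.het),
        "excluded": [
            {"study_id": e.study_id, "reason": e.reason} for e in p.excluded
        ],
    }


def pool_myelotoxicity(
    studies: StudySet,
    model: ModelKind = ModelKind.ALLELE,
    pooling: str = "auto",
    fixed_method: str = "mh",
) -> tuple[PooledResult, list[EffectEstimate]]:
    """Build contrasts, choose fixed vs random by the heterogeneity rule
    (unless overridden), and pool.

    ``pooling``: "auto" applies the I^2/p selection rule; "fixed"/"random"
    force the model.  ``fixed_method``: "mh" (default) or "iv".
    """
    tables = contrasts_for(studies, model)
    if len([t for t in tables if not t.is_double_zero()]) < 1:
        raise ValueError("no informative studies")
    effects = [log_odds_ratio(t) for t in tables]
    fixed = mh_pooled_or(tables) if fixed_method == "mh" else iv_fixed(effects, True)
    if pooling == "fixed":
        return fixed, effects
    random = dl_random(effects, exponentiate=True)
    if pooling == "random":
        return random, effects
    if pooling != "auto":
        raise ValueError(f"unknown pooling {pooling!r}")
    if fixed.het is None:
        return fixed, effects
    return (fixed if select_model(fixed.het) == "FIXED" else random), effects


def run_myelotoxicity(
    studies: StudySet,
    model: ModelKind = ModelKind.ALLELE,
    pooling: str = "auto",
    fixed_method: str = "mh",
    outdir: str | Path | None = None,
) -> dict:
    """Susceptibility meta-analysis with bias tests and leave-one-out."""
    pooled, effects = pool_myelotoxicity(studies, model, pooling, fixed_method)
    included = [e for e in effects if not e.excluded]
    summary: dict = {
        "analysis": "myelotoxicity",
        "model": model.value,
        "pooling_model": "fixed" if pooled.method.endswith("FIXED") else "random",
        "pooled": _pooled_dict(pooled),
    }
    if len(included) >= 3:
        egger = bias_mod.eggers_test(effects)
        begg = bias_mod.beggs_test(effects)
        summary["bias"] = {
            "egger": {"intercept": egger.statistic, "se": egger.se_or_z, "p": egger.p},
            "begg": {"tau": begg.statistic, "z": begg.se_or_z, "p": begg.p},
        }
    if len(included) >= 2:
        tables = [
            t for t in contrasts_for(studies, model) if not t.is_double_zero()
        ]
        loo = bias_mod.leave_one_out(tables, mh_pooled_or)
        summary["leave_one_out"] = {
            "min_estimate": loo.min_estimate,
            "max_estimate": loo.max_estimate,
            "estimates": {
                r.omitted_study_id: r.pooled.estimate for r in loo.results
            },
        }
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        forest_frame(effects, pooled).to_csv(
            outdir / f"forest_{model.value}.tsv", sep="\t", index=False
        )
        tables_to_frame(contrasts_for(studies, model), model).to_csv(
            outdir / f"tables_{model.value}.tsv", sep="\t", index=False
        )
        if len(included) >= 1:
            points, guides = bias_mod.funnel_data(effects, pooled)
            points.to_csv(outdir / f"funnel_points_{model.value}.tsv", sep="\t", index=False)
            guides.to_csv(outdir / f"funnel_guides_{model.value}.tsv", sep="\t", index=False)
        (outdir / f"summary_{model.value}.json").write_text(
            json.dumps(summary, indent=2)
        )
    return summary


def dose_effects(
    studies: StudySet, carrier_policy: str = "drop_sd_less"
) -> list[EffectEstimate]:
    """Per-cohort normalized mean differences, T carriers minus CC.

    Each dose cohort is normalized against its CC group, its carrier group
    formed (published T_CARRIER row, or CT/TT combination under
    ``carrier_policy``), and the unstandardized MD computed on the
    normalized scale (CC mean is exactly 1).
    """
    effects = []
    for s in studies.dose_subset():
        dose = normalize_against_reference(s.dose)
        carrier = carrier_summary(dose, policy=carrier_policy)
        if carrier is None:
            effects.append(
                EffectEstimate(s.study_id, float("nan"), float("nan"), True,
                               "no carrier dose group")
            )
            continue
        effects.append(mean_difference(carrier, dose["CC"], study_id=s.study_id))
    return effects


def run_dose(
    studies: StudySet,
    carrier_policy: str = "drop_sd_less",
    pooling: str = "random",
    outdir: str | Path | None = None,
) -> dict:
    """Dose meta-analysis (DL random effects on the normalized MD scale)."""
    effects = dose_effects(studies, carrier_policy)
    included = [e for e in effects if not e.excluded]
    if len(included) < 2:
        raise ValueError("need at least 2 dose cohorts with usable summaries")
    pooled = (
        dl_random(effects) if pooling == "random" else iv_fixed(effects)
    )
    summary: dict = {
        "analysis": "dose",
        "carrier_policy": carrier_policy,
        "pooled": _pooled_dict(pooled),
        "percent_reduction": abs(pooled.estimate) * 100.0,
    }
    by_disease = {}
    for disease in ("IBD", "ALL"):
        ids = {s.study_id for s in studies.dose_subset() if s.disease == disease}
        sub = [e for e in effects if e.study_id in ids]
        if len([e for e in sub if not e.excluded]) >= 2:
            by_disease[disease] = _pooled_dict(dl_random(sub))
    if by_disease:
        summary["by_disease"] = by_disease
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        forest_frame(effects, pooled).to_csv(outdir / "forest_dose.tsv", sep="\t", index=False)
        (outdir / "summary_dose.json").write_text(json.dumps(summary, indent=2))
    return summary


def run_diagnostics(studies: StudySet, outdir: str | Path | None = None) -> dict:
    """Carrier diagnostic summary and per-genotype event rates."""
    diag = carrier_diagnostics(studies)
    rates = genotype_event_rates(studies)
    summary = {
        "analysis": "diagnostics",
        "tp": diag.tp, "fn": diag.fn, "tn": diag.tn, "fp": diag.fp,
        "sensitivity": diag.sensitivity,
        "specificity": diag.specificity,
        "genotype_rates": rates.pooled,
        "ct_rate_by_study": rates.ct_by_study,
        "ct_rate_min": rates.ct_min,
        "ct_rate_max": rates.ct_max,
        "ct_rate_median": rates.ct_median,
    }
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        (outdir / "summary_diagnostics.json").write_text(json.dumps(summary, indent=2))
    return summary
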