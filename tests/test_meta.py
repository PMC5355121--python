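"""Effect sizes, MH / IV / DL pooling, heterogeneity, model selection."""

import math
import random

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from thiometa.meta import (
    EffectEstimate,
    HeterogeneityResult,
    dl_random,
    heterogeneity,
    iv_fixed,
    log_odds_ratio,
    mean_difference,
    mh_pooled_or,
    select_model,
)
from thiometa.models import ModelKind, TwoByTwo, contrasts_for
from thiometa.simulate import MetaSimConfig, simulate_meta_cohorts
from thiometa.studies import DoseSummary


def t22(a, b, c, d, sid="s"):
    return TwoByTwo(sid, a, b, c, d)


class TestLogOddsRatio:
    def test_symmetric_table(self):
        e = log_odds_ratio(t22(10, 10, 10, 10))
        assert e.effect == 0.0
        assert e.se == pytest.approx(math.sqrt(0.4))

    def test_zero_cell_correction(self):
        # recessive table of the largest IBD cohort: (14, 332, 0, 632)
        e = log_odds_ratio(t22(14, 332, 0, 632))
        assert math.exp(e.effect) == pytest.approx(
            (14.5 * 632.5) / (332.5 * 0.5), rel=1e-12
        )
        assert round(math.exp(e.effect), 2) == 55.17

    def test_double_zero_excluded(self):
        e = log_odds_ratio(t22(0, 46, 0, 5))
        assert e.excluded and "zero" in e.reason


class TestIvFixed:
    def test_identical_effects(self):
        effs = [EffectEstimate(f"s{i}", 0.7, 0.2) for i in range(4)]
        p = iv_fixed(effs)
        assert p.estimate == pytest.approx(0.7)
        assert p.het.Q == pytest.approx(0.0, abs=1e-12)
        assert p.het.i2 == 0.0

    def test_two_effect_closed_form(self):
        p = iv_fixed([EffectEstimate("a", 0.0, 1.0), EffectEstimate("b", 2.0, 1.0)])
        assert p.estimate == pytest.approx(1.0)
        se = (p.ci_high - p.ci_low) / (2 * 1.959963984540054)
        assert se == pytest.approx(math.sqrt(0.5))

    @settings(max_examples=50, derandomize=True, deadline=None)
    @given(st.lists(st.tuples(st.floats(-3, 3), st.floats(0.05, 2)), min_size=1, max_size=10))
    def test_convexity(self, pairs):
        effs = [EffectEstimate(f"s{i}", th, se) for i, (th, se) in enumerate(pairs)]
        p = iv_fixed(effs)
        assert min(e.effect for e in effs) - 1e-9 <= p.estimate <= max(e.effect for e in effs) + 1e-9


class TestHeterogeneity:
    def test_requires_two(self):
        with pytest.raises(ValueError):
            heterogeneity([EffectEstimate("a", 0.0, 1.0)])

    def test_identical_effects_zero(self):
        h = heterogeneity([EffectEstimate(f"s{i}", 1.0, 0.5) for i in range(3)])
        assert h.Q == pytest.approx(0.0, abs=1e-12) and h.i2 == 0.0 and h.tau2 == 0.0

    def test_extreme_separation_approaches_100(self):
        h = heterogeneity([EffectEstimate("a", 0.0, 0.01), EffectEstimate("b", 5.0, 0.01)])
        assert h.i2 > 95

    def test_fixture_allele_model(self, allele_effects):
        h = heterogeneity(allele_effects)
        assert h.i2 == 0.0
        assert h.p == pytest.approx(0.68, abs=0.05)


class TestModelSelection:
    @pytest.mark.parametrize(
        "i2, p, expected",
        [(0.0, 0.68, "FIXED"), (80.0, 0.01, "RANDOM"), (60.0, 0.2, "RANDOM"),
         (30.0, 0.05, "RANDOM"), (49.9, 0.11, "FIXED")],
    )
    def test_rule(self, i2, p, expected):
        het = HeterogeneityResult(Q=10.0, df=5, p=p, i2=i2, tau2=0.1)
        assert select_model(het) == expected


class TestDlRandom:
    def test_reduces_to_fixed_when_homogeneous(self):
        effs = [EffectEstimate(f"s{i}", 0.5, 0.5) for i in range(5)]
        f, r = iv_fixed(effs), dl_random(effs)
        assert r.estimate == pytest.approx(f.estimate)
        assert r.ci_low == pytest.approx(f.ci_low)
        assert r.het.tau2 == 0.0

    def test_tau2_recovery_direct_simulation(self):
        # theta_i ~ N(0, tau2 + se^2) with known within-study se: the moment
        # estimator is unbiased, so the mean over replicates must bracket tau2
        rng = np.random.default_rng(42)
        tau2, se, k, reps = 0.09, 0.2, 20, 500
        est = []
        for _ in range(reps):
            th = rng.normal(0, math.sqrt(tau2 + se**2), size=k)
            effs = [EffectEstimate(f"s{i}", float(t), se) for i, t in enumerate(th)]
            est.append(dl_random(effs).het.tau2)
        mc_se = np.std(est, ddof=1) / math.sqrt(reps)
        assert abs(np.mean(est) - tau2) < 2 * mc_se + 1e-3


class TestMeanDifference:
    def test_identical_groups(self):
        g = DoseSummary(mean=2.0, sd=0.5, n=25, norm_mean=0.8, norm_sd=0.2)
        e = mean_difference(g, g)
        assert e.effect == 0.0

    def test_hand_arithmetic(self):
        g1 = DoseSummary(mean=2, sd=1, n=25, norm_mean=0.7, norm_sd=0.3)
        g2 = DoseSummary(mean=3, sd=1, n=100, norm_mean=1.0, norm_sd=0.4)
        e = mean_difference(g1, g2)
        assert e.effect == pytest.approx(-0.3)
        assert e.se == pytest.approx(math.sqrt(0.0036 + 0.0016))

    def test_singleton_excluded(self):
        g1 = DoseSummary(mean=2, n=1, norm_mean=0.7)
        g2 = DoseSummary(mean=3, sd=1, n=100, norm_mean=1.0, norm_sd=0.4)
        assert mean_difference(g1, g2).excluded


class TestPoolingInvariants:
    def test_mh_iv_agree_on_fixture(self, allele_tables, allele_effects):
        mh = mh_pooled_or(allele_tables)
        iv = iv_fixed(allele_effects, exponentiate=True)
        assert mh.estimate == pytest.approx(iv.estimate, rel=0.02)

    def test_order_and_label_invariance(self, allele_tables):
        ref = mh_pooled_or(allele_tables)
        shuffled = list(allele_tables)
        random.Random(7).shuffle(shuffled)
        relabeled = [
            TwoByTwo(f"r{i}", *t.cells()) for i, t in enumerate(shuffled)
        ]
        p = mh_pooled_or(relabeled)
        assert p.estimate == pytest.approx(ref.estimate, rel=1e-12)
        assert p.ci_low == pytest.approx(ref.ci_low, rel=1e-12)

    def test_exposure_inversion_inverts_or(self, allele_tables):
        ref = mh_pooled_or(allele_tables)
        inverted = [
            TwoByTwo(t.study_id, t.case_unexposed, t.case_exposed,
                     t.control_unexposed, t.control_exposed)
            for t in allele_tables
        ]
        p = mh_pooled_or(inverted)
        assert p.estimate == pytest.approx(1.0 / ref.estimate, rel=1e-12)

    def test_single_study_identity(self):
        t = t22(20, 80, 10, 90)
        p = mh_pooled_or([t])
        assert p.estimate == pytest.approx((20 * 90) / (80 * 10), rel=1e-12)
        assert p.het is None


def test_parameter_recovery_under_true_or():
    """Pooled log OR is unbiased and its 95% CI calibrated on simulated
    7-study ensembles with the fixture's arm sizes and a true allele OR of 8."""
    reps = 200
    ln_ors, covered = [], 0
    for r in range(reps):
        ss = simulate_meta_cohorts(MetaSimConfig(seed=10_000 + r))
        tables = contrasts_for(ss, ModelKind.ALLELE)
        p = mh_pooled_or(tables)
        ln_ors.append(math.log(p.estimate))
        covered += p.ci_low <= 8.0 <= p.ci_high
    mc_se = np.std(ln_ors, ddof=1) / math.sqrt(reps)
    assert abs(np.mean(ln_ors) - math.log(8.0)) < 2 * mc_se + 0.02
    assert 0.90 <= covered / reps <= 0.99
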