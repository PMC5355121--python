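"""Additive-dosage eQTL regression and scan behaviour."""

import numpy as np
import pytest
from scipy import stats

from thiometa.eqtl import (
    ConstantDosageError,
    ExpressionVector,
    GenotypePanel,
    SnpRecord,
    align,
    filter_snps,
    read_dosage_matrix,
    read_expression,
    regional_table,
    regress,
    scan,
    write_dosage_matrix,
)
from thiometa.simulate import EqtlSimConfig, simulate_eqtl_panel


def _panel(dosage, ids=None):
    dosage = np.asarray(dosage, dtype=float)
    n, m = dosage.shape
    snps = tuple(SnpRecord(f"rs{j}", "13", 48582000 + j) for j in range(m))
    samples = tuple(ids or (f"S{i}" for i in range(n)))
    return GenotypePanel(samples, snps, dosage)


class TestFilter:
    @pytest.mark.parametrize("carriers, kept", [(2, False), (3, True), (0, False)])
    def test_min_carrier_boundary(self, carriers, kept):
        col = np.zeros(10)
        col[:carriers] = 1
        p = filter_snps(_panel(col[:, None]), min_carriers=3)
        assert p.n_snps == (1 if kept else 0)

    def test_missing_not_counted_as_carrier(self):
        col = np.array([1.0, 1.0, np.nan, 0, 0])
        assert filter_snps(_panel(col[:, None]), 3).n_snps == 0


class TestRegress:
    def test_perfect_linear_fit(self):
        dosage = np.array([0, 0, 1, 1, 2, 2], dtype=float)
        r = regress(2 * dosage + 1, dosage, "rs1")
        assert r.beta == pytest.approx(2.0)
        assert r.p == pytest.approx(np.finfo(float).tiny)

    def test_two_group_equals_t_test(self):
        rng = np.random.default_rng(5)
        dosage = np.repeat([0.0, 1.0], 15)
        y = rng.normal(0, 1, 30) + 0.8 * dosage
        r = regress(y, dosage)
        t, p = stats.ttest_ind(y[dosage == 1], y[dosage == 0], equal_var=True)
        assert r.beta == pytest.approx(y[dosage == 1].mean() - y[dosage == 0].mean())
        assert r.t == pytest.approx(float(t))
        assert r.p == pytest.approx(float(p))

    def test_constant_dosage_raises(self):
        with pytest.raises(ConstantDosageError):
            regress(np.arange(5.0), np.ones(5))

    def test_equivariance_under_expression_scaling(self):
        rng = np.random.default_rng(6)
        dosage = rng.binomial(2, 0.3, 40).astype(float)
        y = rng.normal(0, 1, 40)
        a, b = regress(y, dosage), regress(10 * y, dosage)
        assert b.beta == pytest.approx(10 * a.beta)
        assert b.se == pytest.approx(10 * a.se)
        assert b.t == pytest.approx(a.t) and b.p == pytest.approx(a.p)

    def test_pairwise_deletion(self):
        dosage = np.array([0, 1, 2, np.nan, 1, 0], dtype=float)
        y = np.arange(6.0)
        r = regress(y, dosage)
        ref = regress(y[~np.isnan(dosage)], dosage[~np.isnan(dosage)])
        assert r.n == 5 and r.beta == pytest.approx(ref.beta)


class TestScan:
    def test_matches_single_snp_regression(self):
        panel, expr = simulate_eqtl_panel(EqtlSimConfig(n_samples=80, n_snps=25, seed=3))
        dosage = panel.dosage.copy()
        dosage[::7, ::3] = np.nan  # inject missingness
        panel = GenotypePanel(panel.sample_ids, panel.snps, dosage)
        df = scan(panel, expr).set_index("snp_id")
        for j, snp in enumerate(panel.snps):
            row = df.loc[snp.id]
            try:
                ref = regress(expr.values, dosage[:, j], snp.id)
            except ConstantDosageError:
                assert bool(row["skipped"])
                continue
            assert row["beta"] == pytest.approx(ref.beta, rel=1e-9)
            assert row["se"] == pytest.approx(ref.se, rel=1e-9)
            assert row["p"] == pytest.approx(ref.p, rel=1e-9)
            assert row["n"] == ref.n

    def test_output_is_permutation_of_input(self):
        panel, expr = simulate_eqtl_panel(EqtlSimConfig(n_samples=50, n_snps=12, seed=4))
        df = scan(panel, expr)
        assert sorted(df["snp_id"]) == sorted(s.id for s in panel.snps)
        assert (df["p"].diff().dropna() >= 0).all()

    def test_single_snp_scan_equals_regress(self):
        panel, expr = simulate_eqtl_panel(EqtlSimConfig(n_samples=60, n_snps=1, seed=8))
        df = scan(panel, expr)
        ref = regress(expr.values, panel.dosage[:, 0])
        assert df.loc[0, "beta"] == pytest.approx(ref.beta)

    def test_planted_effect_recovered_at_panel_scale(self):
        """beta_hat within 2 SE of the planted slope at n = 447, MAF 0.2."""
        cfg = EqtlSimConfig(n_samples=447, n_snps=1, maf_range=(0.2, 0.2),
                            causal_beta=-0.5, causal_index=0, seed=21)
        panel, expr = simulate_eqtl_panel(cfg)
        r = regress(expr.values, panel.dosage[:, 0])
        assert abs(r.beta - (-0.5)) < 2 * r.se

    def test_causal_snp_usually_top_hit(self):
        hits = 0
        for rep in range(100):
            panel, expr = simulate_eqtl_panel(
                EqtlSimConfig(n_samples=447, n_snps=50, seed=300 + rep)
            )
            top = scan(filter_snps(panel), expr).iloc[0]
            hits += top["snp_id"] == "rs_causal"
        assert hits >= 90

    def test_null_minimum_p_uniform_order_statistic(self):
        """With no causal effect, the smallest p over m variants follows
        Beta(1, m); its probability transform must look uniform (KS)."""
        mins, m = [], 100
        for rep in range(500):
            panel, expr = simulate_eqtl_panel(
                EqtlSimConfig(n_samples=100, n_snps=m, causal_beta=0.0, seed=7000 + rep)
            )
            mins.append(scan(panel, expr)["p"].iloc[0])
        u = 1 - (1 - np.array(mins)) ** m
        assert stats.kstest(u, "uniform").pvalue > 0.01

    def test_regional_table_position_sorted(self):
        panel, expr = simulate_eqtl_panel(EqtlSimConfig(n_samples=50, n_snps=10, seed=9))
        reg = regional_table(scan(panel, expr))
        assert (reg["pos"].diff().dropna() > 0).all()
        assert set(reg.columns) == {"chrom", "pos", "snp_id", "p", "neg_log10_p"}


class TestIO:
    def test_dosage_matrix_round_trip(self, tmp_path):
        panel, _ = simulate_eqtl_panel(EqtlSimConfig(n_samples=12, n_snps=5, seed=2))
        d = panel.dosage.copy()
        d[0, 0] = np.nan
        panel = GenotypePanel(panel.sample_ids, panel.snps, d)
        p2 = read_dosage_matrix(write_dosage_matrix(panel, tmp_path / "g.tsv"))
        assert p2.sample_ids == panel.sample_ids
        assert p2.snps == panel.snps
        np.testing.assert_array_equal(p2.dosage, panel.dosage)

    def test_expression_reader_and_align(self, tmp_path):
        p = tmp_path / "e.tsv"
        p.write_text("S2\t1.5\nS0\t-0.5\nS9\t2.0\n")
        expr = read_expression(p)
        panel = _panel(np.array([[0.0], [1.0], [2.0]]), ids=["S0", "S1", "S2"])
        pa, ea = align(panel, expr)
        assert pa.sample_ids == ("S0", "S2")
        np.testing.assert_array_equal(ea.values, [-0.5, 1.5])
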