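"""Welch tests, median-difference selection, and edge differential correlation."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import drivernet as dn
from drivernet.differential_stats import welch_pvalues
from tests.conftest import tiny_cohort


def closed_form_welch_p(a, b):
    """Independent oracle: Welch t and Welch-Satterthwaite df from the formulas."""
    na, nb = len(a), len(b)
    ma, mb = np.mean(a), np.mean(b)
    va, vb = np.var(a, ddof=1), np.var(b, ddof=1)
    se2 = va / na + vb / nb
    if se2 == 0:
        return 1.0
    t = (ma - mb) / math.sqrt(se2)
    df = se2**2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
    return 2 * stats.t.sf(abs(t), df)


def make_expr(X, prefix="P"):
    probes = [f"{prefix}{i:04d}" for i in range(X.shape[0])]
    samples = [f"s{i}" for i in range(X.shape[1])]
    expr = pd.DataFrame(X, index=probes, columns=samples)
    pm = pd.Series({p: f"G{p[1:]}" for p in probes})
    return expr, pm, samples


class TestWelch:
    def test_agrees_with_closed_form_on_random_inputs(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(300, 25))
        p = welch_pvalues(X[:, :10], X[:, 10:])
        expected = [closed_form_welch_p(row[:10], row[10:]) for row in X]
        assert np.max(np.abs(p - expected)) < 1e-10

    def test_identical_groups_give_p_one(self):
        a = np.tile(np.arange(5.0), (3, 1))
        assert (welch_pvalues(a, a) == 1.0).all()

    def test_zero_variance_both_groups_equal_means(self):
        a = np.full((2, 4), 3.0)
        assert (welch_pvalues(a, a) == 1.0).all()


class TestDifferentialExpression:
    def test_extreme_probe_selected_by_both_criteria(self):
        rng = np.random.default_rng(1)
        X = rng.normal(0, 1, size=(100, 10))
        X[0, :5] = 10 + rng.normal(0, 0.01, 5)
        X[0, 5:] = 0 + rng.normal(0, 0.01, 5)
        expr, pm, samples = make_expr(X)
        labels = pd.Series(["TN"] * 5 + ["ER"] * 5, index=samples)
        de = dn.differential_expression(expr, pm, labels, "TN")
        assert "P0000" in de.selected_probes
        assert de.selected_by["P0000"] == "both"
        assert "G0000" in de.selected_genes

    def test_planted_probes_recovered(self):
        """20 probes shifted by 3 SD (n=20 vs 40) land in the selection."""
        rng = np.random.default_rng(2)
        X = rng.normal(size=(1000, 60))
        planted = list(range(20))
        X[np.ix_(planted, range(20))] += 3.0
        expr, pm, samples = make_expr(X)
        labels = pd.Series(["TN"] * 20 + ["ER"] * 40, index=samples)
        de = dn.differential_expression(expr, pm, labels, "TN")
        recovered = sum(f"P{i:04d}" in de.selected_probes for i in planted)
        assert recovered >= 18

    def test_selection_fraction_honoured(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(500, 30))
        expr, pm, samples = make_expr(X)
        labels = pd.Series(["TN"] * 10 + ["ER"] * 20, index=samples)
        de = dn.differential_expression(expr, pm, labels, "TN",
                                        top_frac_p=0.02, top_frac_median=0.01)
        by_p = (de.p_values <= de.p_cutoff).sum()
        assert by_p <= math.ceil(0.02 * 500) + 1  # +1 would indicate a tie
        assert len(de.selected_probes) <= by_p + math.ceil(0.01 * 500)

    def test_downregulated_probe_never_selected(self):
        rng = np.random.default_rng(4)
        X = rng.normal(size=(100, 20))
        X[0, :8] -= 5.0  # strongly UNDERexpressed in the subtype: tiny p
        expr, pm, samples = make_expr(X)
        labels = pd.Series(["TN"] * 8 + ["ER"] * 12, index=samples)
        de = dn.differential_expression(expr, pm, labels, "TN")
        assert de.p_values["P0000"] < de.p_cutoff
        assert "P0000" not in de.selected_probes

    def test_degenerate_group_sizes_error(self):
        expr, pm, samples = make_expr(np.zeros((5, 3)))
        labels = pd.Series(["TN", "ER", "ER"], index=samples)
        with pytest.raises(ValueError):
            dn.differential_expression(expr, pm, labels, "TN")

    def test_bonferroni_flag_recorded(self):
        rng = np.random.default_rng(5)
        X = rng.normal(size=(200, 30))
        X[0, :10] += 8.0
        expr, pm, samples = make_expr(X)
        labels = pd.Series(["TN"] * 10 + ["ER"] * 20, index=samples)
        de = dn.differential_expression(expr, pm, labels, "TN")
        assert bool(de.bonferroni_significant["P0000"])
        assert de.p_values["P0000"] <= 0.05 / 200


class TestEdgeDifferentialCorrelation:
    def make_cohort(self, g1, g2, labels):
        n = len(g1)
        return tiny_cohort(
            expr_rows={"G1_p1": g1, "G2_p1": g2},
            cna_rows={"G1": [0] * n, "G2": [0] * n},
            labels=labels)

    def test_matches_covariance_formula_on_toy_vectors(self):
        rng = np.random.default_rng(6)
        g1, g2 = rng.normal(size=10), rng.normal(size=10)
        labels = {f"s{i}": ("TN" if i < 5 else "ER") for i in range(10)}
        cohort = self.make_cohort(g1, g2, labels)
        res = dn.edge_differential_correlation(
            ("G1", "G2"), cohort.expression, cohort.probe_map, cohort.labels, "TN")
        r_in = stats.pearsonr(g1[:5], g2[:5]).statistic
        r_out = stats.pearsonr(g1[5:], g2[5:]).statistic
        assert res.r_in == pytest.approx(r_in, abs=1e-12)
        assert res.r_out == pytest.approx(r_out, abs=1e-12)
        assert res.delta == pytest.approx(r_in - r_out, abs=1e-12)

    def test_symmetric_in_endpoints(self):
        rng = np.random.default_rng(7)
        g1, g2 = rng.normal(size=12), rng.normal(size=12)
        labels = {f"s{i}": ("TN" if i < 6 else "ER") for i in range(12)}
        cohort = self.make_cohort(g1, g2, labels)
        ab = dn.edge_differential_correlation(
            ("G1", "G2"), cohort.expression, cohort.probe_map, cohort.labels, "TN")
        ba = dn.edge_differential_correlation(
            ("G2", "G1"), cohort.expression, cohort.probe_map, cohort.labels, "TN")
        assert ab.delta == pytest.approx(ba.delta, abs=1e-12)

    def test_identical_in_subtype_independent_outside(self):
        rng = np.random.default_rng(8)
        shared = rng.normal(size=30)
        g1 = np.concatenate([shared, rng.normal(size=30)])
        g2 = np.concatenate([shared, rng.normal(size=30)])
        labels = {f"s{i}": ("TN" if i < 30 else "ER") for i in range(60)}
        cohort = self.make_cohort(g1, g2, labels)
        res = dn.edge_differential_correlation(
            ("G1", "G2"), cohort.expression, cohort.probe_map, cohort.labels, "TN")
        assert res.r_in == pytest.approx(1.0)
        assert abs(res.r_out) < 0.5
        assert res.delta > 0.5

    def test_constant_vector_degenerate_not_dropped(self):
        g1 = np.concatenate([np.full(5, 2.0), np.random.default_rng(9).normal(size=5)])
        g2 = np.random.default_rng(10).normal(size=10)
        labels = {f"s{i}": ("TN" if i < 5 else "ER") for i in range(10)}
        cohort = self.make_cohort(g1, g2, labels)
        res = dn.edge_differential_correlation(
            ("G1", "G2"), cohort.expression, cohort.probe_map, cohort.labels, "TN")
        assert res.r_in == 0.0
        assert res.degenerate

    def test_multiprobe_uses_pair_with_max_abs_in_subtype_r(self):
        rng = np.random.default_rng(11)
        base = rng.normal(size=12)
        g1_noisy = base + rng.normal(0, 3, 12)
        g1_clean = base + rng.normal(0, 0.1, 12)
        g2 = base + rng.normal(0, 0.1, 12)
        labels = {f"s{i}": ("TN" if i < 6 else "ER") for i in range(12)}
        cohort = tiny_cohort(
            expr_rows={"G1_p1": g1_noisy, "G1_p2": g1_clean, "G2_p1": g2},
            cna_rows={"G1": [0] * 12, "G2": [0] * 12},
            labels=labels,
            probe_map={"G1_p1": "G1", "G1_p2": "G1", "G2_p1": "G2"})
        res = dn.edge_differential_correlation(
            ("G1", "G2"), cohort.expression, cohort.probe_map, cohort.labels, "TN")
        best = max(
            (stats.pearsonr(v[:6], g2[:6]).statistic for v in (g1_noisy, g1_clean)),
            key=abs)
        assert res.r_in == pytest.approx(best, abs=1e-12)
        assert res.probe_a == "G1_p2"


class TestCoexpressionThreshold:
    def test_selects_exactly_the_extreme_tail(self):
        deltas = np.concatenate([np.zeros(1000), [1.5, 1.5]])
        thr = dn.coexpression_threshold(deltas, top_frac=0.002)
        assert (deltas >= thr).sum() == 2

    def test_full_fraction_returns_min(self):
        deltas = np.array([0.3, -0.2, 0.9])
        assert dn.coexpression_threshold(deltas, 1.0) == pytest.approx(-0.2)

    def test_single_element(self):
        assert dn.coexpression_threshold([0.42]) == pytest.approx(0.42)

    def test_qualifying_fraction_near_target(self):
        rng = np.random.default_rng(12)
        deltas = rng.normal(size=5000)
        thr = dn.coexpression_threshold(deltas, 0.002)
        assert (deltas >= thr).sum() == 10
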