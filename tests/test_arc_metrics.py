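import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from psem.arc_metrics import arc_force_kl, arc_report, g_test, mutual_information
from psem.bayesnet import DAGStructure, fit_cpts_mle, loglik_bits
from psem.structure import tabu_search, MDLConfig
from tests.conftest import random_categorical_frame


def mi_double_sum(table):
    """Textbook double-sum MI in bits."""
    table = np.asarray(table, float)
    n = table.sum()
    out = 0.0
    for i in range(table.shape[0]):
        for j in range(table.shape[1]):
            pij = table[i, j] / n
            if pij > 0:
                out += pij * np.log2(
                    pij / (table[i].sum() / n * table[:, j].sum() / n))
    return out


def expand(table):
    xs, ys = [], []
    for i in range(table.shape[0]):
        for j in range(table.shape[1]):
            xs += [i] * int(table[i, j])
            ys += [j] * int(table[i, j])
    return np.array(xs), np.array(ys)


class TestMutualInformation:
    def test_independent_table_zero(self):
        x, y = expand(np.array([[25, 25], [25, 25]]))
        assert mutual_information(x, y) == pytest.approx(0.0, abs=1e-12)

    def test_diagonal_table_one_bit(self):
        x, y = expand(np.array([[50, 0], [0, 50]]))
        assert mutual_information(x, y) == pytest.approx(1.0)

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_double_sum_on_random_tables(self, seed):
        rng = np.random.default_rng(seed)
        table = rng.integers(0, 30, size=(3, 4))
        table[0, 0] += 1  # non-empty
        x, y = expand(table)
        assert mutual_information(x, y) == pytest.approx(
            mi_double_sum(table), abs=1e-12)

    def test_conditional_mi_matches_stratified_sum(self):
        rng = np.random.default_rng(3)
        x = rng.integers(0, 2, 500)
        z = rng.integers(0, 3, 500)
        y = (x + z + (rng.random(500) < 0.2)) % 3
        expected = sum(
            (z == s).mean() * mutual_information(x[z == s], y[z == s])
            for s in range(3))
        assert mutual_information(x, y, z) == pytest.approx(expected, abs=1e-12)

    def test_bounded_by_marginal_entropies(self):
        rng = np.random.default_rng(4)
        x = rng.integers(0, 3, 200)
        y = rng.integers(0, 4, 200)
        mi = mutual_information(x, y)
        hx = stats.entropy(np.bincount(x), base=2)
        hy = stats.entropy(np.bincount(y), base=2)
        assert 0 <= mi <= min(hx, hy) + 1e-12


class TestArcForce:
    def test_deterministic_copy_is_one_bit(self):
        rng = np.random.default_rng(0)
        a = rng.integers(0, 2, 400)
        df = pd.DataFrame({"A": a, "B": a})
        s = DAGStructure({"A": 2, "B": 2}, {"B": ("A",)})
        bn = fit_cpts_mle(s, df)
        assert arc_force_kl(bn, ("A", "B"), df) == pytest.approx(
            mutual_information(a, a))

    def test_independent_pair_near_zero(self):
        rng = np.random.default_rng(1)
        df = random_categorical_frame(rng, 1000, [2, 2]).rename(
            columns={"V0": "A", "V1": "B"})
        s = DAGStructure({"A": 2, "B": 2}, {"B": ("A",)})
        bn = fit_cpts_mle(s, df)
        assert arc_force_kl(bn, ("A", "B"), df) < 0.01

    @pytest.mark.parametrize("seed", range(5))
    def test_equals_empirical_joint_kl_route(self, seed):
        """Two independent routes: conditional MI vs explicit per-sample
        log-likelihood ratio of the networks with and without the arc."""
        rng = np.random.default_rng(seed)
        df = random_categorical_frame(rng, 150, [2, 3, 2, 2])
        arities = {f"V{i}": a for i, a in enumerate([2, 3, 2, 2])}
        s_with = DAGStructure(arities, {"V1": ("V0",), "V3": ("V1", "V2")})
        s_without = DAGStructure(arities, {"V1": ("V0",), "V3": ("V2",)})
        bn = fit_cpts_mle(s_with, df)
        bn0 = fit_cpts_mle(s_without, df)
        kl_route = (loglik_bits(bn0, df) - loglik_bits(bn, df)) / len(df)
        assert arc_force_kl(bn, ("V1", "V3"), df) == pytest.approx(
            kl_route, abs=1e-9)

    def test_removing_weakest_arc_loglik_identity(self):
        rng = np.random.default_rng(6)
        df = random_categorical_frame(rng, 200, [2, 2, 3])
        g = tabu_search(df, MDLConfig(sc=0.05, seed=0))
        if not g.arcs:
            pytest.skip("no arcs learned at this sc")
        bn = fit_cpts_mle(g, df)
        forces = {a: arc_force_kl(bn, a, df) for a in g.arcs}
        weakest = min(forces, key=forces.get)
        parents = {v: tuple(p for p in g.parents[v]
                            if (p, v) != weakest)
                   for v in g.nodes}
        bn0 = fit_cpts_mle(DAGStructure(g.arities, parents), df)
        assert loglik_bits(bn0, df) - loglik_bits(bn, df) == pytest.approx(
            len(df) * forces[weakest], abs=1e-6)

    def test_invariant_to_category_relabeling(self):
        rng = np.random.default_rng(7)
        a = rng.integers(0, 3, 300)
        b = (a + rng.integers(0, 2, 300)) % 3
        df = pd.DataFrame({"A": a, "B": b})
        s = DAGStructure({"A": 3, "B": 3}, {"B": ("A",)})
        f1 = arc_force_kl(fit_cpts_mle(s, df), ("A", "B"), df)
        perm = np.array([2, 0, 1])
        df2 = pd.DataFrame({"A": perm[a], "B": perm[b]})
        f2 = arc_force_kl(fit_cpts_mle(s, df2), ("A", "B"), df2)
        assert f1 == pytest.approx(f2, abs=1e-12)


class TestGTest:
    def test_independent_table_g_zero(self):
        x, y = expand(np.array([[25, 25], [25, 25]]))
        g, df_, p = g_test(x, y)
        assert g == pytest.approx(0.0, abs=1e-9)
        assert p == pytest.approx(1.0)

    def test_matches_cellwise_classical_formula(self):
        table = np.array([[40, 10], [10, 40]])
        x, y = expand(table)
        g, df_, p = g_test(x, y)
        n = table.sum()
        expect = 0.0
        for i in range(2):
            for j in range(2):
                e = table[i].sum() * table[:, j].sum() / n
                expect += 2 * table[i, j] * np.log(table[i, j] / e)
        assert g == pytest.approx(expect, abs=1e-9)
        assert df_ == 1

    def test_degenerate_variable_rejected(self):
        with pytest.raises(ValueError, match="df"):
            g_test(np.zeros(10, int), np.arange(10) % 2)

    def test_null_calibration(self):
        rng = np.random.default_rng(11)
        rej = sum(
            g_test(rng.integers(0, 2, 100), rng.integers(0, 2, 100))[2] < 0.05
            for _ in range(400))
        assert 0.02 <= rej / 400 <= 0.08

    def test_pvalues_approximately_uniform_under_null(self):
        rng = np.random.default_rng(12)
        ps = [g_test(rng.integers(0, 2, 120), rng.integers(0, 2, 120))[2]
              for _ in range(1000)]
        # KS against uniform; G-test p-values are discrete, so alpha loose
        stat, p = stats.kstest(ps, "uniform")
        assert p > 0.001


class TestArcReport:
    def test_report_rows_match_columnwise_recomputation(self):
        rng = np.random.default_rng(13)
        a = rng.integers(0, 3, 250)
        b = (a + (rng.random(250) < 0.25)) % 3
        c = rng.integers(0, 2, 250)
        df = pd.DataFrame({"A": a, "B": b, "C": c})
        raw = pd.DataFrame({"A": a + rng.normal(0, .1, 250),
                            "B": b + rng.normal(0, .1, 250),
                            "C": c + rng.normal(0, .1, 250)})
        s = DAGStructure({"A": 3, "B": 3, "C": 2}, {"B": ("A", "C")})
        bn = fit_cpts_mle(s, df)
        rep = arc_report(bn, df, raw)
        row = rep[(rep.parent == "A") & (rep.child == "B")].iloc[0]
        assert row.KL == pytest.approx(
            mutual_information(a, b, c), abs=1e-12)
        g, df_, p = g_test(a, b, c)
        assert row.G == pytest.approx(g) and row.df == df_
        m = ~(raw.A.isna() | raw.B.isna())
        assert row.r == pytest.approx(
            stats.pearsonr(raw.A[m], raw.B[m])[0])
        # sorted by descending force, deterministic copy-like arc on top
        assert rep.KL.is_monotonic_decreasing

    def test_nonlinear_relation_high_kl_modest_r(self):
        rng = np.random.default_rng(14)
        x = rng.normal(size=400)
        y = np.abs(x) + rng.normal(0, 0.05, 400)  # strong, non-monotone
        xq = np.digitize(x, np.quantile(x, [0.25, 0.5, 0.75]))
        yq = np.digitize(y, np.quantile(y, [0.25, 0.5, 0.75]))
        df = pd.DataFrame({"X": xq, "Y": yq})
        s = DAGStructure({"X": 4, "Y": 4}, {"Y": ("X",)})
        bn = fit_cpts_mle(s, df)
        rep = arc_report(bn, df, pd.DataFrame({"X": x, "Y": y}))
        row = rep.iloc[0]
        assert row.KL > 0.5
        assert abs(row.r) < 0.4
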