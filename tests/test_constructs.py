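import numpy as np
import pandas as pd
import pytest

from psem.bayesnet import DAGStructure
from psem.constructs import (
    NaiveBayesModel,
    VariableClustering,
    cluster_variables,
    contingency_table_fit,
    fit_latent_naive_bayes,
    jackknife_cluster_stability,
    lc_scores,
    purity,
)


def entropy_bits(counts):
    p = np.asarray(counts, float)
    p = p[p > 0] / p.sum()
    return float(-(p * np.log2(p)).sum())


@pytest.fixture()
def hidden_coin_members():
    """Two binary members that copy a hidden fair coin, N=500."""
    rng = np.random.default_rng(0)
    z = rng.integers(0, 2, 500)
    flip = lambda v: np.where(rng.random(500) < 0.05, 1 - v, v)
    return pd.DataFrame({"m1": flip(z), "m2": flip(z)}), z


class TestClustering:
    def test_partition_and_size_invariants(self):
        with pytest.raises(ValueError, match="two clusters"):
            VariableClustering([["a"], ["a", "b"]])
        with pytest.raises(ValueError, match="size"):
            VariableClustering([[f"t{i}" for i in range(11)]])

    def test_disconnected_components_stay_apart(self):
        rng = np.random.default_rng(1)
        a = rng.integers(0, 2, 300)
        b = (a + (rng.random(300) < 0.1)) % 2
        c = rng.integers(0, 2, 300)
        d = (c + (rng.random(300) < 0.1)) % 2
        df = pd.DataFrame({"A": a, "B": b, "C": c, "D": d})
        s = DAGStructure({v: 2 for v in "ABCD"},
                         {"B": ("A",), "D": ("C",)})
        cl = cluster_variables(s, df)
        assert len(cl.clusters) >= 2
        groups = {frozenset(c) for c in cl.clusters}
        assert frozenset(("A", "B")) in groups
        assert frozenset(("C", "D")) in groups

    def test_max_size_forces_split_of_large_clique(self):
        rng = np.random.default_rng(2)
        z = rng.integers(0, 2, 400)
        cols = {f"t{i:02d}": (z + (rng.random(400) < 0.05)) % 2
                for i in range(12)}
        df = pd.DataFrame(cols)
        names = sorted(cols)
        parents = {names[i + 1]: (names[i],) for i in range(11)}
        s = DAGStructure({n: 2 for n in names}, parents)
        cl = cluster_variables(s, df, max_size=10)
        assert len(cl.clusters) >= 2
        assert all(len(c) <= 10 for c in cl.clusters)

    def test_planted_constructs_recovered(self, study_dataset):
        from sklearn.metrics import adjusted_rand_score

        from psem.discretize import apply_binning, r2_optimal_discretize
        from psem.preprocess import (compute_relative_abundances,
                                     filter_low_abundance,
                                     log_transform_nonzero)
        from psem.structure import MDLConfig, tabu_search

        counts, meta, truth = study_dataset
        table = compute_relative_abundances(counts, meta)
        filt, _ = filter_low_abundance(table)
        logra = log_transform_nonzero(filt)
        disc = {}
        for t in logra.index:
            b = r2_optimal_discretize(logra.loc[t].to_numpy(float), variable=t)
            disc[t] = apply_binning(logra.loc[t].to_numpy(float), b)
        disc = pd.DataFrame(disc, index=logra.columns)
        net = tabu_search(disc, MDLConfig(sc=0.3, seed=0, n_restarts=2))
        cl = cluster_variables(net, disc)
        taxa = sorted(net.nodes)
        lab = {g: i for i, (c, gs) in
               enumerate(sorted(truth.membership.items())) for g in gs}
        ari = adjusted_rand_score([lab[t] for t in taxa], cl.labels(taxa))
        assert ari >= 0.9


class TestLatentNaiveBayes:
    def test_hidden_coin_recovery(self, hidden_coin_members):
        df, z = hidden_coin_members
        model = fit_latent_naive_bayes(df, 2, seed=0)
        # each member CPT should be within 0.05 of the true 0.95/0.05 table
        for cpt in model.cpts:
            peak = cpt.max(axis=1)
            assert (peak > 0.9).all()
        post = model.posteriors(df).argmax(axis=1)
        acc = max((post == z).mean(), (post == 1 - z).mean())
        # Bayes-optimal ceiling is ~0.95: disagreeing members are a coin flip
        assert acc > 0.92

    def test_single_member_cluster_mirrors_member(self):
        df = pd.DataFrame({"only": [0, 1, 2, 1, 0, 2, 1, 1]})
        model = fit_latent_naive_bayes(df, 3, seed=0)
        post = model.posteriors(df)
        assert (post.argmax(axis=1) == df["only"].to_numpy()).all()

    def test_loglik_improves_with_more_restarts_never_worse(self):
        rng = np.random.default_rng(5)
        z = rng.integers(0, 3, 300)
        df = pd.DataFrame({
            f"m{i}": (z + (rng.random(300) < 0.1)) % 3 for i in range(3)})
        one = fit_latent_naive_bayes(df, 3, seed=1, n_em_restarts=1)
        many = fit_latent_naive_bayes(df, 3, seed=1, n_em_restarts=5)
        assert many.loglik >= one.loglik - 1e-6

    def test_states_ordered_by_member_level(self, hidden_coin_members):
        df, _ = hidden_coin_members
        model = fit_latent_naive_bayes(df, 2, seed=0)
        # canonical order: higher state implies higher expected member value
        mean0 = sum(cpt[0] @ np.arange(cpt.shape[1]) for cpt in model.cpts)
        mean1 = sum(cpt[1] @ np.arange(cpt.shape[1]) for cpt in model.cpts)
        assert mean1 > mean0

    def test_weights_max_one(self, hidden_coin_members):
        df, _ = hidden_coin_members
        model = fit_latent_naive_bayes(df, 2, seed=0)
        mi = model.member_mi()
        w = mi / mi.max()
        assert w.max() == pytest.approx(1.0)
        assert ((w > 0) & (w <= 1)).all()


class TestQualityMetrics:
    def test_deterministic_members_purity_100(self):
        z = np.repeat([0, 1], 50)
        df = pd.DataFrame({"m1": z, "m2": z})
        model = fit_latent_naive_bayes(df, 2, seed=0)
        assert purity(model, df) == pytest.approx(100.0, abs=0.1)

    def test_uninformative_latent_purity_half(self):
        df = pd.DataFrame({"m1": [0, 1] * 50, "m2": [0, 0, 1, 1] * 25})
        model = NaiveBayesModel(
            ["m1", "m2"], np.array([0.5, 0.5]),
            [np.full((2, 2), 0.5), np.full((2, 2), 0.5)], 0.0)
        assert purity(model, df) == pytest.approx(50.0)

    def test_ctf_hand_computed_three_members(self):
        rng = np.random.default_rng(8)
        z = rng.integers(0, 2, 400)
        df = pd.DataFrame({
            f"m{i}": (z + (rng.random(400) < 0.15)) % 2 for i in range(3)})
        model = fit_latent_naive_bayes(df, 2, seed=0)
        ctf = contingency_table_fit(model, df)
        # oracle entropies by full tabulation
        N = len(df)
        h_ind = sum(entropy_bits(np.bincount(df[m])) for m in df)
        patterns = df.m0 * 4 + df.m1 * 2 + df.m2
        h_joint = entropy_bits(np.bincount(patterns))
        h_nb = float(-model.sample_log2lik(df).mean())
        expect = np.clip(100 * (h_ind - h_nb) / (h_ind - h_joint), 0, 100)
        assert ctf == pytest.approx(expect, abs=1e-9)

    def test_independent_members_ctf_undefined(self):
        # balanced factorial design: members exactly independent
        df = pd.DataFrame({"m1": [0, 0, 1, 1] * 10, "m2": [0, 1, 0, 1] * 10})
        model = NaiveBayesModel(
            ["m1", "m2"], np.array([1.0]),
            [np.full((1, 2), 0.5), np.full((1, 2), 0.5)], 0.0)
        with pytest.warns(UserWarning):
            assert contingency_table_fit(model, df) is None

    def test_purity_invariant_to_member_order(self, hidden_coin_members):
        df, _ = hidden_coin_members
        m1 = fit_latent_naive_bayes(df, 2, seed=0)
        m2 = fit_latent_naive_bayes(df[["m2", "m1"]], 2, seed=0)
        assert purity(m1, df) == pytest.approx(purity(m2, df), abs=0.5)


class TestScores:
    def test_single_member_score_is_member_value(self):
        v = np.array([[0.5], [1.5], [-2.0]])
        np.testing.assert_allclose(lc_scores(np.array([1.0]), v),
                                   v.ravel())

    def test_equal_weights_average(self):
        v = np.array([[-2.0, -4.0]])
        assert lc_scores(np.array([1.0, 1.0]), v)[0] == pytest.approx(-3.0)

    def test_weighted_average_hand_value(self):
        v = np.array([[0.0, -3.0]])
        assert lc_scores(np.array([1.0, 0.5]), v)[0] == pytest.approx(-1.0)

    def test_zero_marks_use_below_minimum_sentinel(self):
        v = np.array([[np.nan, -2.0], [-4.0, -2.0]])
        out = lc_scores(np.array([1.0, 1.0]), v)
        # member 0 minimum is -4, sentinel -5
        assert out[0] == pytest.approx((-5.0 - 2.0) / 2)


class TestJackknife:
    def test_deterministic_clusters_fully_stable(self):
        rng = np.random.default_rng(10)
        z1 = rng.integers(0, 2, 200)
        z2 = rng.integers(0, 2, 200)
        df = pd.DataFrame({"a1": z1, "a2": z1, "b1": z2, "b2": z2})
        ref = VariableClustering([["a1", "a2"], ["b1", "b2"]])

        def learn(sub):
            from psem.structure import MDLConfig, tabu_search

            return tabu_search(sub, MDLConfig(sc=0.5, seed=0))

        out = jackknife_cluster_stability(df, ref, learn, folds=5, seed=0)
        assert out["mean_correspondence_pct"].min() == pytest.approx(100.0)
        assert out.attrs["overall_mean_pct"] == pytest.approx(100.0)

    def test_correspondence_bounded(self):
        rng = np.random.default_rng(11)
        df = pd.DataFrame({f"t{i}": rng.integers(0, 2, 120)
                           for i in range(6)})
        ref = VariableClustering([["t0", "t1", "t2"], ["t3", "t4", "t5"]])

        def learn(sub):
            from psem.structure import MDLConfig, tabu_search

            return tabu_search(sub, MDLConfig(sc=0.3, seed=0))

        out = jackknife_cluster_stability(df, ref, learn, folds=4, seed=0)
        assert ((out["mean_correspondence_pct"] >= 0)
                & (out["mean_correspondence_pct"] <= 100)).all()
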