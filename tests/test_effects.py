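import numpy as np
import pandas as pd
import pytest

from psem.bayesnet import DAGStructure, DiscreteBN, fit_cpts_mle
from psem.effects import (
    StructuralDataset,
    auc_rank,
    crossval_target_auc,
    direct_effect,
    effect_significance,
    learn_structural_model,
    total_effect,
)
from psem.structure import MDLConfig


def linear_chain_bn(slope=1.0, n_cat=3):
    """X -> Y with E[Y|X=x] = slope * x exactly (by CPT construction)."""
    arities = {"X": n_cat, "Y": 2 * n_cat - 1}
    s = DAGStructure(arities, {"Y": ("X",)})
    px = np.full(n_cat, 1 / n_cat)
    # Y representatives 0..2(n-1) scaled by 0.5 -> mean slope*x for slope=1
    cpt = np.zeros((n_cat, 2 * n_cat - 1))
    for x in range(n_cat):
        # spread over 2x and its neighbours with mean exactly 2x * 0.5 = x
        cpt[x, 2 * x] = 1.0
    bn = DiscreteBN(s, {"X": px, "Y": cpt})
    # Y takes value 2x, so representatives 0.5*slope*j give E[Y|x] = slope*x
    reps = {"X": np.arange(n_cat, dtype=float),
            "Y": 0.5 * slope * np.arange(2 * n_cat - 1, dtype=float)}
    data = pd.DataFrame({"X": [0], "Y": [0]})
    ds = StructuralDataset(data, reps, target="Y")
    return bn, ds


@pytest.fixture()
def mediation_bn():
    """Z -> M -> Y plus Z -> Y: M's direct effect on Y is zero."""
    arities = {"Z": 3, "M": 3, "Y": 3}
    s = DAGStructure(arities, {"M": ("Z",), "Y": ("Z",)})
    noisy = np.array([[0.8, 0.15, 0.05],
                      [0.1, 0.8, 0.1],
                      [0.05, 0.15, 0.8]])
    bn = DiscreteBN(s, {"Z": np.array([0.3, 0.4, 0.3]),
                        "M": noisy, "Y": noisy})
    reps = {v: np.arange(3, dtype=float) for v in arities}
    ds = StructuralDataset(pd.DataFrame({v: [0] for v in arities}), reps,
                           target="Y")
    return bn, ds


class TestTotalEffect:
    def test_deterministic_linear_chain_slope_one(self):
        bn, ds = linear_chain_bn()
        assert total_effect(bn, ds, "X") == pytest.approx(1.0, rel=1e-6)

    def test_no_path_gives_zero(self):
        arities = {"A": 2, "B": 2}
        s = DAGStructure(arities)
        bn = DiscreteBN(s, {"A": np.array([0.4, 0.6]),
                            "B": np.array([0.7, 0.3])})
        ds = StructuralDataset(pd.DataFrame({"A": [0], "B": [0]}),
                               {"A": np.array([0.0, 1.0]),
                                "B": np.array([0.0, 1.0])}, target="B")
        assert abs(total_effect(bn, ds, "A")) < 1e-9

    def test_local_linearity_across_delta(self, mediation_bn):
        bn, ds = mediation_bn
        t1 = total_effect(bn, ds, "M", delta=0.05)
        t2 = total_effect(bn, ds, "M", delta=0.1)
        assert t1 == pytest.approx(t2, rel=0.05)

    def test_single_category_source_rejected(self):
        arities = {"A": 1, "B": 2}
        s = DAGStructure(arities)
        bn = DiscreteBN(s, {"A": np.array([1.0]),
                            "B": np.array([0.5, 0.5])})
        ds = StructuralDataset(pd.DataFrame({"A": [0], "B": [0]}),
                               {"A": np.array([0.0]),
                                "B": np.array([0.0, 1.0])}, target="B")
        with pytest.raises(ValueError, match="single"):
            total_effect(bn, ds, "A")


class TestDirectEffect:
    def test_deterministic_linear_function_direct_equals_total(self):
        bn, ds = linear_chain_bn()
        d = direct_effect(bn, ds, "X")
        t = total_effect(bn, ds, "X")
        assert d == pytest.approx(1.0, rel=1e-6)
        assert d == pytest.approx(t, rel=1e-4)

    def test_mediated_source_has_zero_direct_nonzero_total(self, mediation_bn):
        bn, ds = mediation_bn
        assert direct_effect(bn, ds, "M") == 0.0
        assert abs(total_effect(bn, ds, "M")) > 0.1

    def test_confounded_nonparent_zero_direct(self):
        # Z -> X, Z -> Y: X is not a parent of Y
        arities = {"Z": 2, "X": 2, "Y": 2}
        s = DAGStructure(arities, {"X": ("Z",), "Y": ("Z",)})
        flip = np.array([[0.9, 0.1], [0.1, 0.9]])
        bn = DiscreteBN(s, {"Z": np.array([0.5, 0.5]), "X": flip, "Y": flip})
        reps = {v: np.arange(2, dtype=float) for v in arities}
        ds = StructuralDataset(pd.DataFrame({v: [0] for v in arities}), reps,
                               target="Y")
        assert direct_effect(bn, ds, "X") == 0.0

    def test_adjusted_slope_with_two_parents_hand_value(self):
        # Y has parents X and C; E[Y | x, c] = x + 2c by construction
        arities = {"X": 2, "C": 2, "Y": 4}
        s = DAGStructure(arities, {"Y": ("X", "C")})
        cpt = np.zeros((2, 2, 4))
        for x in range(2):
            for c in range(2):
                cpt[x, c, x + 2 * c] = 1.0
        bn = DiscreteBN(s, {"X": np.array([0.5, 0.5]),
                            "C": np.array([0.25, 0.75]), "Y": cpt})
        reps = {"X": np.arange(2.0), "C": np.arange(2.0),
                "Y": np.arange(4.0)}
        ds = StructuralDataset(pd.DataFrame({v: [0] for v in arities}), reps,
                               target="Y")
        assert direct_effect(bn, ds, "X") == pytest.approx(1.0, abs=1e-9)
        assert direct_effect(bn, ds, "C") == pytest.approx(2.0, abs=1e-9)

    def test_standardized_invariant_to_target_affine_rescale(self):
        bn, ds = linear_chain_bn()
        from psem.effects import standardized

        t = total_effect(bn, ds, "X")
        s1 = standardized(bn, ds, "X", t)
        ds2 = StructuralDataset(ds.data,
                                {"X": ds.representatives["X"],
                                 "Y": 3.0 * ds.representatives["Y"] + 7.0},
                                target="Y")
        t2 = total_effect(bn, ds2, "X")
        s2 = standardized(bn, ds2, "X", t2)
        assert s1 == pytest.approx(s2, rel=1e-9)


class TestAUC:
    def test_rank_auc_matches_trapezoid_integration(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            scores = rng.normal(size=60)
            labels = (rng.random(60) < 0.4).astype(int)
            if labels.sum() in (0, 60):
                continue
            # independent oracle: explicit ROC trapezoid
            from sklearn.metrics import roc_auc_score

            assert auc_rank(scores, labels) == pytest.approx(
                roc_auc_score(labels, scores), abs=1e-12)

    def test_perfect_separation_auc_one(self):
        assert auc_rank(np.array([0.1, 0.2, 0.9, 0.95]),
                        np.array([0, 0, 1, 1])) == 1.0


class TestStructuralLearning:
    def test_degenerate_bagging_reduces_to_plain_search(self):
        rng = np.random.default_rng(1)
        z = rng.integers(0, 2, 200)
        df = pd.DataFrame({"A": z, "B": (z + (rng.random(200) < 0.1)) % 2,
                           "C": rng.integers(0, 2, 200)})
        ds = StructuralDataset(df, {v: np.arange(2.0) for v in df},
                               target="C")
        bn, freq = learn_structural_model(ds, sc=1.0, n_boot=1,
                                          freq_threshold=1.0, seed=0)
        from psem.structure import tabu_search

        plain = tabu_search(df, MDLConfig(sc=1.0, seed=0))
        assert set(bn.structure.arcs) == set(plain.arcs)

    def test_arc_frequencies_bounded_and_prior_retained(self):
        rng = np.random.default_rng(2)
        z = rng.integers(0, 3, 150)
        df = pd.DataFrame({"A": z, "B": (z + (rng.random(150) < 0.1)) % 3,
                           "C": rng.integers(0, 2, 150)})
        ds = StructuralDataset(df, {"A": np.arange(3.0),
                                    "B": np.arange(3.0),
                                    "C": np.arange(2.0)}, target="C")
        bn, freq = learn_structural_model(ds, sc=0.8, n_boot=20, seed=0)
        assert ((freq["frequency"] > 0) & (freq["frequency"] <= 1)).all()
        strong = freq[freq.frequency >= 0.5]
        got = {frozenset(a) for a in bn.structure.arcs}
        for _, row in strong.iterrows():
            assert frozenset((row.parent, row.child)) in got


class TestCrossval:
    def test_perfectly_predictive_feature_auc_one(self):
        rng = np.random.default_rng(3)
        y = rng.integers(0, 2, 120)
        df = pd.DataFrame({"X": y, "Y": y})
        ds = StructuralDataset(df, {"X": np.arange(2.0),
                                    "Y": np.arange(2.0)}, target="Y")
        auc = crossval_target_auc(ds, sc=1.0, folds=4, seed=0)
        assert auc["auc"].min() > 0.99

    def test_shuffled_labels_auc_near_half(self):
        rng = np.random.default_rng(4)
        df = pd.DataFrame({"X": rng.integers(0, 2, 300),
                           "Y": rng.integers(0, 2, 300)})
        ds = StructuralDataset(df, {"X": np.arange(2.0),
                                    "Y": np.arange(2.0)}, target="Y")
        auc = crossval_target_auc(ds, sc=1.0, folds=5, seed=0)
        assert auc.attrs["macro_auc"] == pytest.approx(0.5, abs=0.07)


class TestSignificance:
    def test_strong_effect_ci_excludes_zero_noise_ci_covers(self):
        rng = np.random.default_rng(5)
        x = rng.integers(0, 3, 250)
        y = np.clip(x + rng.integers(-1, 2, 250), 0, 3)
        noise = rng.integers(0, 2, 250)
        df = pd.DataFrame({"X": x, "N": noise, "Y": y})
        ds = StructuralDataset(df, {"X": np.arange(3.0),
                                    "N": np.arange(2.0),
                                    "Y": np.arange(4.0)}, target="Y")
        bn, _ = learn_structural_model(ds, sc=0.5, n_boot=1,
                                       freq_threshold=1.0, seed=0)
        est = effect_significance(ds, bn, ["X", "N"], n_boot=60, seed=0)
        by = {e.source: e for e in est}
        assert by["X"].significant_total
        assert not by["N"].significant_total

    def test_ci_width_shrinks_with_sample_size(self):
        def build(n, seed):
            rng = np.random.default_rng(seed)
            x = rng.integers(0, 3, n)
            y = np.clip(x + rng.integers(-1, 2, n), 0, 3)
            df = pd.DataFrame({"X": x, "Y": y})
            return StructuralDataset(df, {"X": np.arange(3.0),
                                          "Y": np.arange(4.0)}, target="Y")

        widths = []
        for n in (100, 400):
            ds = build(n, 6)
            bn, _ = learn_structural_model(ds, sc=0.5, n_boot=1,
                                           freq_threshold=1.0, seed=0)
            est = effect_significance(ds, bn, ["X"], n_boot=80, seed=0)
            widths.append(est[0].ci_total[1] - est[0].ci_total[0])
        assert widths[1] < widths[0]
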