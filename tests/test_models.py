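"""Elastic net, conditional forest, importances and evaluation."""

import numpy as np
import pandas as pd
import pytest

from ironomics import models
from ironomics.models import (
    ConditionalForest,
    ModelFit,
    downsample_balance,
    dynamic_ir_experiment,
    evaluate,
    expression_stratified_experiment,
    fit_conditional_forest,
    fit_elastic_net,
    permutation_importance,
    rank_features_en,
)


def logistic_table(n=600, p=10, weights=None, seed=0, label_noise=0.0):
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(n, p))
    w = np.zeros(p)
    if weights:
        for i, v in weights.items():
            w[i] = v
    prob = 1 / (1 + np.exp(-(X @ w)))
    y = rng.binomial(1, prob)
    if label_noise:
        flip = rng.random(n) < label_noise
        y = np.where(flip, 1 - y, y)
    tab = pd.DataFrame(X, columns=[f"f{i}" for i in range(p)])
    tab["label"] = np.where(y == 1, "retained", "non_retained")
    return tab, [f"f{i}" for i in range(p)]


class TestDownsample:
    def test_majority_reduced_to_minority(self):
        tab = pd.DataFrame({"label": ["retained"] * 900
                            + ["non_retained"] * 100, "x": range(1000)})
        out = downsample_balance(tab, seed=0)
        assert out["label"].value_counts().tolist() == [100, 100]

    def test_balanced_input_unchanged(self):
        tab = pd.DataFrame({"label": ["retained"] * 50
                            + ["non_retained"] * 50, "x": range(100)})
        assert len(downsample_balance(tab, seed=0)) == 100

    def test_deterministic_given_seed(self):
        tab = pd.DataFrame({"label": ["retained"] * 300
                            + ["non_retained"] * 100, "x": range(400)})
        a = downsample_balance(tab, seed=5)
        b = downsample_balance(tab, seed=5)
        pd.testing.assert_frame_equal(a, b)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            downsample_balance(pd.DataFrame({"label": ["retained"] * 5}), 0)


class TestElasticNet:
    def test_informative_feature_kept_noise_shrunk(self):
        tab, names = logistic_table(n=500, weights={2: 3.0}, seed=1)
        fit = fit_elastic_net(tab, names, seed=1)
        ranking = rank_features_en(fit)
        assert ranking.top(1) == ["f2"]
        # elastic net shrinks the noise block to near zero
        noise = ranking.importances.drop("f2")
        assert noise.max() < 0.2

    def test_constant_feature_dropped(self):
        tab, names = logistic_table(n=300, weights={0: 2.0}, seed=2)
        tab["f5"] = 1.0
        fit = fit_elastic_net(tab, names, seed=2)
        assert fit.dropped == ["f5"]
        assert "f5" not in fit.feature_names

    def test_null_labels_give_chance_auc(self):
        tab, names = logistic_table(n=500, weights=None, seed=3)
        fit = fit_elastic_net(tab, names, seed=3)
        assert 0.40 <= fit.cv_auc <= 0.60

    def test_same_seed_identical_coefficients(self):
        tab, names = logistic_table(n=300, weights={2: 2.0}, seed=5)
        a = fit_elastic_net(tab, names, seed=7)
        b = fit_elastic_net(tab, names, seed=7)
        assert np.array_equal(a.coef, b.coef)
        assert a.hyperparameters == b.hyperparameters

    def test_prediction_pipeline_roundtrip(self):
        tab, names = logistic_table(n=500, weights={1: 2.5}, seed=4)
        fit = fit_elastic_net(tab, names, seed=4)
        proba = fit.predict_proba(tab[fit.feature_names].to_numpy(float))
        assert proba.shape == (500,) and (0 <= proba).all() and (proba <= 1).all()


class TestRankEn:
    def fake_fit(self, coef):
        return ModelFit(kind="EN", feature_names=[f"f{i}" for i in
                                                  range(len(coef))],
                        hyperparameters={}, seed=0, coef=np.array(coef),
                        intercept=0.0, scaler_mean=np.zeros(len(coef)),
                        scaler_sd=np.ones(len(coef)))

    def test_absolute_value_normalization(self):
        r = rank_features_en(self.fake_fit([2.0, -1.0, 0.0]))
        assert np.allclose(r.importances, [2 / 3, 1 / 3, 0.0])

    def test_all_zero_flagged(self):
        r = rank_features_en(self.fake_fit([0.0, 0.0]))
        assert r.all_zero and (r.importances == 0).all()

    def test_scale_invariance(self):
        a = rank_features_en(self.fake_fit([2.0, -1.0, 0.5]))
        b = rank_features_en(self.fake_fit([4.0, -2.0, 1.0]))
        assert np.allclose(a.importances, b.importances)


class TestConditionalForest:
    def test_separating_binary_feature_wins_root(self):
        rng = np.random.default_rng(5)
        n = 400
        X = rng.normal(size=(n, 21))
        X[:, 0] = rng.integers(0, 2, n)
        y = X[:, 0].astype(int)
        # consider every feature at the root: the association test must put
        # the separating binary feature first despite its low cardinality
        forest = ConditionalForest(n_trees=60, mtry=21, seed=5).fit(X, y)
        roots = [t.feature[0] for t in forest.trees]
        frac = np.mean([f == 0 for f in roots])
        assert frac >= 0.95

    def test_pure_node_becomes_leaf(self):
        X = np.ones((50, 3))
        y = np.ones(50, dtype=int)
        forest = ConditionalForest(n_trees=5, seed=0).fit(X, y)
        for t in forest.trees:
            assert len(t.feature) == 1 and t.feature[0] == -1

    def test_same_seed_identical_predictions(self):
        tab, names = logistic_table(n=300, weights={0: 2.0}, seed=6)
        X = tab[names].to_numpy(float)
        y = (tab["label"] == "retained").astype(int).to_numpy()
        p1 = ConditionalForest(n_trees=30, seed=7).fit(X, y).predict_proba(X)
        p2 = ConditionalForest(n_trees=30, seed=7).fit(X, y).predict_proba(X)
        assert np.array_equal(p1, p2)

    def test_oob_proba_defined_for_most_rows(self):
        tab, names = logistic_table(n=200, weights={0: 2.0}, seed=8)
        X = tab[names].to_numpy(float)
        y = (tab["label"] == "retained").astype(int).to_numpy()
        f = ConditionalForest(n_trees=50, seed=8).fit(X, y)
        oob = f.oob_proba(X)
        assert np.isfinite(oob).mean() > 0.95


class TestPermutationImportance:
    def test_informative_feature_dominates(self):
        tab, names = logistic_table(n=600, weights={3: 3.0}, seed=9)
        fit = fit_conditional_forest(tab, names, n_trees=60, seed=9)
        r = permutation_importance(fit, tab)
        assert r.top(1) == ["f3"]
        assert r.importances["f3"] > 0.5

    def test_importances_sum_to_one(self):
        tab, names = logistic_table(n=400, weights={0: 2.0, 5: -2.0}, seed=10)
        fit = fit_conditional_forest(tab, names, n_trees=40, seed=10)
        r = permutation_importance(fit, tab)
        assert r.importances.sum() == pytest.approx(1.0, abs=1e-9)
        assert (r.importances >= 0).all()

    def test_pure_noise_near_zero(self):
        tab, names = logistic_table(n=600, weights={1: 3.0}, seed=11)
        fit = fit_conditional_forest(tab, names, n_trees=60, seed=11)
        r = permutation_importance(fit, tab)
        noise = r.importances.drop("f1")
        assert noise.max() < 0.15


class TestEvaluate:
    def perfect_fit(self, tab, names):
        y = (tab["label"] == "retained").astype(int).to_numpy()
        fit = ModelFit(kind="EN", feature_names=["score"], hyperparameters={},
                       seed=0, coef=np.array([10.0]), intercept=0.0,
                       scaler_mean=np.zeros(1), scaler_sd=np.ones(1))
        return fit

    def test_perfect_scores(self):
        y = np.array([0, 0, 1, 1] * 25)
        tab = pd.DataFrame({"score": y.astype(float),
                            "label": np.where(y == 1, "retained",
                                              "non_retained")})
        fit = self.perfect_fit(tab, ["score"])
        res = evaluate(fit, tab)
        assert res.auc == 1.0 and res.pr_auc == 1.0

    def test_reversed_scores_complement(self):
        rng = np.random.default_rng(12)
        y = rng.integers(0, 2, 200)
        s = rng.normal(size=200) + y
        tab = pd.DataFrame({"score": s, "label": np.where(y == 1, "retained",
                                                          "non_retained")})
        fit = self.perfect_fit(tab, ["score"])
        auc = evaluate(fit, tab).auc
        tab2 = tab.assign(score=-tab["score"])
        assert evaluate(fit, tab2).auc == pytest.approx(1 - auc, abs=1e-12)

    def test_single_class_undefined(self):
        tab = pd.DataFrame({"score": [0.1, 0.2], "label": ["retained"] * 2})
        res = evaluate(self.perfect_fit(tab, ["score"]), tab)
        assert res.auc is None


class TestExperiments:
    def test_dynamic_experiment_refuses_underpowered(self):
        tab, names = logistic_table(n=100, weights={0: 2.0}, seed=13)
        tab["intron_id"] = [f"i{k}" for k in range(100)]
        with pytest.raises(ValueError, match="underpowered"):
            dynamic_ir_experiment(tab, {"i0", "i1"}, seed=13)

    def test_expression_strata_boundaries(self):
        tab, names = logistic_table(n=120, weights={0: 2.0}, seed=14)
        tab["intron_id"] = [f"i{k}" for k in range(120)]
        dyn = {f"i{k}" for k in range(120)}
        log2fc = {f"i{k}": 0.0 for k in range(120)}
        log2fc["i0"] = 2.0    # boundary: stable (<= 2)
        log2fc["i1"] = 2.1    # up
        log2fc["i2"] = -3.0   # down
        out = expression_stratified_experiment(tab, log2fc, dyn, seed=14,
                                               n_trees=20)
        assert out["strata_sizes"]["up"] == 1
        assert out["strata_sizes"]["down"] == 1
        assert out["strata_sizes"]["stable"] == 118
        assert "crf_auc" in out


def test_cross_cell_type_generalization_with_shared_weights():
    """Shared planted weights across cell types: off-diagonal AUC close to
    diagonal; cell-type-specific weights: off-diagonal markedly lower."""
    shared = {}
    for k, ct in enumerate(["A", "B"]):
        tab, names = logistic_table(n=500, weights={0: 2.5, 1: 2.0},
                                    seed=20 + k)
        shared[ct] = tab
    mat = models.cross_cell_type_eval(shared, names, kind="cRF", seed=1,
                                      n_trees=40)
    assert mat.loc["A", "B"] > 0.75 and mat.loc["B", "A"] > 0.75

    specific = {}
    specific["A"], _ = logistic_table(n=500, weights={0: 3.0}, seed=30)
    specific["B"], _ = logistic_table(n=500, weights={7: 3.0}, seed=31)
    mat2 = models.cross_cell_type_eval(specific, names, kind="cRF", seed=1,
                                       n_trees=40)
    assert mat2.loc["A", "B"] < mat2.loc["A", "A"] - 0.2
    assert mat2.loc["B", "A"] < mat2.loc["B", "B"] - 0.2
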