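"""Registry contracts, single-config tuning, and the auto-ensemble."""

import numpy as np
import pytest

import simguided as sg
from simguided.learners import hard_labels


@pytest.fixture(scope="module")
def easy_classification():
    rng = np.random.default_rng(0)
    z = np.where(rng.random(120) < 0.5, 1.0, -1.0)
    X = np.outer(z, rng.standard_normal(5)) + 0.1 * rng.standard_normal((120, 5))
    return X, (z > 0).astype(float)


class TestRegistries:
    def test_classification_inventory_frozen(self):
        reg = sg.classification_registry()
        assert len(reg) == 21
        assert len({c.family for c in reg}) == 8
        assert len({c.id for c in reg}) == 21
        assert all(c.task == "classification" for c in reg)

    def test_regression_inventory_frozen(self):
        reg = sg.regression_registry()
        assert len(reg) == 32
        assert len({c.family for c in reg}) == 9
        assert len({c.id for c in reg}) == 32
        assert all(c.task == "regression" for c in reg)

    def test_every_bayes_opt_config_has_bounded_space(self):
        for cfg in sg.classification_registry() + sg.regression_registry():
            if cfg.mode == "bayes_opt":
                assert cfg.space is not None
                for d in cfg.space.dimensions:
                    assert d.choices is not None or \
                        (np.isfinite(d.low) and np.isfinite(d.high))
            else:
                assert cfg.build(seed=0) is not None

    def test_mix_of_modes(self):
        modes = {c.mode for c in sg.classification_registry()}
        assert modes == {"defaults", "bayes_opt"}


class TestTuneAndFit:
    def test_defaults_mode_uses_declared_defaults(self, easy_classification):
        X, y = easy_classification
        model = sg.tune_and_fit(sg.get_config("logreg_default"), X, y, seed=1)
        assert model.params == {}

    def test_incumbent_at_least_as_good_as_default(self, easy_classification):
        X, y = easy_classification
        cfg = sg.get_config("svm_rbf_bo")
        from simguided.learners import inner_cv_score
        from simguided.simulate import stage_seed
        model = sg.tune_and_fit(cfg, X, y, n_opt_iters=8, seed=2)
        assert model.inner_cv_score is not None
        default_score = inner_cv_score(cfg, cfg.default_params(), X, y, 3,
                                       stage_seed(2, "inner_folds"))
        # optimizer evaluated the default first, so it can never be beaten by it
        assert model.inner_cv_score >= default_score - 1e-12

    def test_chosen_params_inside_search_space(self, easy_classification):
        X, y = easy_classification
        cfg = sg.get_config("tree_ensemble_bo")
        model = sg.tune_and_fit(cfg, X, y, n_opt_iters=6, seed=3)
        assert cfg.space.contains(model.params)

    def test_deterministic_given_seed(self, easy_classification):
        X, y = easy_classification
        cfg = sg.get_config("logreg_bo")
        a = sg.tune_and_fit(cfg, X, y, n_opt_iters=8, seed=4)
        b = sg.tune_and_fit(cfg, X, y, n_opt_iters=8, seed=4)
        assert a.params == b.params

    def test_single_class_labels_rejected(self):
        X = np.zeros((10, 2))
        with pytest.raises(ValueError, match="single class"):
            sg.tune_and_fit(sg.get_config("logreg_default"), X, np.ones(10))

    def test_missing_values_rejected(self, easy_classification):
        X, y = easy_classification
        X = X.copy()
        X[0, 0] = np.nan
        with pytest.raises(ValueError, match="impute"):
            sg.tune_and_fit(sg.get_config("logreg_default"), X, y)


class TestPredict:
    def test_classifier_scores_bounded(self, easy_classification):
        X, y = easy_classification
        for cid in ("logreg_default", "svm_rbf_default", "knn_default",
                    "naive_bayes_default"):
            model = sg.tune_and_fit(sg.get_config(cid), X, y, seed=0)
            s = sg.predict(model, X)
            assert np.all((s >= 0) & (s <= 1))

    def test_majority_baseline_predicts_training_majority(self):
        rng = np.random.default_rng(1)
        X = rng.standard_normal((30, 3))
        y = np.array([1.0] * 20 + [0.0] * 10)
        model = sg.tune_and_fit(sg.baseline_config("classification"), X, y)
        labels = hard_labels(sg.predict(model, rng.standard_normal((15, 3))))
        assert (labels == 1).all()

    def test_tie_score_assigned_class_one(self):
        assert hard_labels(np.array([0.5, 0.49, 0.51])).tolist() == [1, 0, 1]


class TestAutoEnsemble:
    @pytest.mark.parametrize("cap", [1, 4, 40])
    def test_member_cap_respected(self, easy_classification, cap):
        X, y = easy_classification
        spec = sg.EnsembleSearchSpec(budget=12, max_ensemble_size=cap, seed=5)
        em = sg.auto_ensemble_fit(X, y, spec,
                                  registry=sg.classification_registry())
        assert len(em.members) <= cap
        if cap == 1:
            assert len(em.members) == 1
            assert em.members[0][1] == 1.0

    def test_weights_sum_to_one(self, easy_classification):
        X, y = easy_classification
        spec = sg.EnsembleSearchSpec(budget=15, max_ensemble_size=4, seed=6)
        em = sg.auto_ensemble_fit(X, y, spec,
                                  registry=sg.classification_registry())
        assert sum(w for _, w in em.members) == pytest.approx(1.0)

    def test_greedy_ensemble_no_worse_than_best_member(self,
                                                       easy_classification):
        X, y = easy_classification
        spec = sg.EnsembleSearchSpec(budget=15, max_ensemble_size=4, seed=7)
        em = sg.auto_ensemble_fit(X, y, spec,
                                  registry=sg.classification_registry())
        best_member = max(m.inner_cv_score for m, _ in em.members)
        assert em.inner_cv_score >= best_member - 1e-12

    def test_ensemble_of_identical_members_equals_single(self,
                                                         easy_classification):
        X, y = easy_classification
        m = sg.tune_and_fit(sg.get_config("logreg_default"), X, y, seed=0)
        em = sg.EnsembleModel(members=[(m, 0.5), (m, 0.5)],
                              task="classification")
        np.testing.assert_allclose(em.predict(X), m.predict(X))

    def test_deterministic_given_seed(self, easy_classification):
        X, y = easy_classification
        spec = sg.EnsembleSearchSpec(budget=10, max_ensemble_size=4, seed=8)
        a = sg.auto_ensemble_fit(X, y, spec,
                                 registry=sg.classification_registry())
        b = sg.auto_ensemble_fit(X, y, spec,
                                 registry=sg.classification_registry())
        assert [(m.config.id, w) for m, w in a.members] == \
            [(m.config.id, w) for m, w in b.members]

    def test_budget_as_evaluation_count_is_exact(self, easy_classification):
        # a budget of n evaluations never evaluates more than n candidates
        X, y = easy_classification
        spec = sg.EnsembleSearchSpec(budget=5, max_ensemble_size=2, seed=9)
        em = sg.auto_ensemble_fit(X, y, spec,
                                  registry=sg.classification_registry())
        assert len(em.members) <= 5
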