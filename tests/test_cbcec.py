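import numpy as np
import pytest

from hfens.cbcec import (
    FAMILY_ORDER,
    BaggedEstimator,
    BaseLearnerSpec,
    SelectionResult,
    TrainedEnsemble,
    fit_bagged,
    fit_cbcec,
    run_ablation,
    select_best,
    train_base,
)
from hfens.core_data import SplitPlan, apply_minmax, fit_minmax, make_splits
from hfens.synthetic_data import GeneratorConfig, generate

from conftest import make_table


def separable_table(n=40, seed=0):
    rng = np.random.default_rng(seed)
    X = np.vstack([rng.normal(0, 0.3, (n // 2, 2)),
                   rng.normal(5, 0.3, (n - n // 2, 2))])
    y = np.array([0] * (n // 2) + [1] * (n - n // 2))
    return make_table(X, y)


class _StubLearner:
    """Fixed-probability learner for voting arithmetic tests."""

    def __init__(self, probs):
        self.probs = np.asarray(probs, dtype=float)
        self.spec = BaseLearnerSpec("DT")

    def predict_probability(self, X):
        return np.tile(self.probs, (len(X), 1))

    def predict_label(self, X):
        return np.argmax(self.predict_probability(X), axis=1)


class TestTrainBase:
    @pytest.mark.parametrize("family", FAMILY_ORDER)
    def test_separable_training_accuracy_is_one(self, family):
        t = separable_table()
        fitted = train_base(BaseLearnerSpec(family), t)
        assert (fitted.predict_label(t.X) == t.y).all()

    @pytest.mark.parametrize("family", FAMILY_ORDER)
    def test_probability_simplex(self, family):
        t = separable_table()
        p = train_base(BaseLearnerSpec(family), t).predict_probability(t.X)
        assert p.shape == (t.n, 2)
        np.testing.assert_allclose(p.sum(axis=1), 1.0, atol=1e-9)
        assert (p >= 0).all()

    def test_same_seed_identical_predictions(self):
        t = separable_table(seed=3)
        a = train_base(BaseLearnerSpec("ET", seed=7), t)
        b = train_base(BaseLearnerSpec("ET", seed=7), t)
        np.testing.assert_array_equal(a.predict_probability(t.X),
                                      b.predict_probability(t.X))

    def test_single_class_rejected(self):
        t = make_table(np.arange(6, dtype=float), [1] * 6)
        with pytest.raises(ValueError, match="single-class"):
            train_base(BaseLearnerSpec("DT"), t)

    def test_unknown_family_rejected(self):
        with pytest.raises(ValueError):
            BaseLearnerSpec("XGB")


class TestSelectBest:
    def test_printed_score_table_argmax(self):
        # argmax over an accuracy table must pick the top row
        res = SelectionResult(
            scores={"DT": 0.8875, "GB": 0.8974, "SVM": 0.875, "ET": 0.90},
            chosen_family="ET",
        )
        assert res.chosen_family == "ET"
        with pytest.raises(ValueError):
            SelectionResult(scores=res.scores, chosen_family="DT")

    def test_selection_trains_and_scores_each_family(self):
        t = separable_table(n=60)
        tr, va = make_splits(t, SplitPlan(train_fractions=(0.7,), seed=0))[0]
        res = select_best([BaseLearnerSpec(f) for f in FAMILY_ORDER], tr, va)
        assert set(res.scores) == set(FAMILY_ORDER)
        assert res.scores[res.chosen_family] == max(res.scores.values())

    def test_all_tied_scores_pick_first_fixed_order(self):
        t = separable_table(n=60)  # every family is perfect here
        tr, va = make_splits(t, SplitPlan(train_fractions=(0.7,), seed=0))[0]
        res = select_best([BaseLearnerSpec(f) for f in FAMILY_ORDER], tr, va)
        assert res.chosen_family == "DT"

    def test_needs_two_families_and_nonempty_validation(self):
        t = separable_table()
        with pytest.raises(ValueError):
            select_best([BaseLearnerSpec("DT")], t, t)


class TestBagging:
    def test_aggregate_is_mean_of_member_probabilities(self):
        bag = BaggedEstimator(
            base=BaseLearnerSpec("DT"), B=2,
            members=[_StubLearner([0.6, 0.4]), _StubLearner([0.2, 0.8])],
            bootstrap_indices=[np.arange(2)] * 2,
        )
        np.testing.assert_allclose(bag.predict_probability(np.zeros((3, 2))),
                                   [[0.4, 0.6]] * 3)

    def test_bootstrap_indices_fixed_by_seed(self):
        t = separable_table()
        a = fit_bagged(BaseLearnerSpec("DT"), t, B=4, seed=11)
        b = fit_bagged(BaseLearnerSpec("DT"), t, B=4, seed=11)
        for ia, ib in zip(a.bootstrap_indices, b.bootstrap_indices):
            np.testing.assert_array_equal(ia, ib)
        assert all(len(i) == t.n for i in a.bootstrap_indices)

    def test_members_see_both_classes(self):
        t = make_table(np.arange(12, dtype=float), [0] * 10 + [1] * 2)
        bag = fit_bagged(BaseLearnerSpec("DT"), t, B=10, seed=0)
        for idx in bag.bootstrap_indices:
            assert len(np.unique(t.y[idx])) == 2

    def test_bagging_reduces_probability_variance(self):
        """Aggregated test probabilities vary less across refits than single trees."""
        t = generate(GeneratorConfig(n_samples=300, minority_fraction=0.4, seed=0))
        scaled = apply_minmax(fit_minmax(t), t)
        tr, te = make_splits(scaled, SplitPlan(train_fractions=(0.7,), seed=0))[0]
        single, bagged = [], []
        for seed in range(10):
            spec = BaseLearnerSpec("DT", seed=seed)
            single.append(train_base(spec, tr).predict_probability(te.X)[:, 1])
            bagged.append(fit_bagged(spec, tr, B=10, seed=seed)
                          .predict_probability(te.X)[:, 1])
        assert np.var(bagged, axis=0).mean() <= np.var(single, axis=0).mean()


class TestVoting:
    def test_soft_vote_hand_arithmetic(self):
        ens = TrainedEnsemble(bp_c=_StubLearner([0.6, 0.4]),
                              b_bg=_StubLearner([0.2, 0.8]), voting="soft")
        X = np.zeros((1, 2))
        np.testing.assert_allclose(ens.predict_probability(X), [[0.4, 0.6]])
        assert ens.predict_label(X).tolist() == [1]

    def test_probabilities_stay_on_simplex(self):
        t = separable_table(n=60)
        ens = fit_cbcec(t, B=3, seed=1)
        p = ens.predict_probability(t.X)
        np.testing.assert_allclose(p.sum(axis=1), 1.0)

    def test_vote_among_clones_equals_the_clone(self):
        t = separable_table(n=60)
        bp_c = train_base(BaseLearnerSpec("GB"), t)
        bag = BaggedEstimator(base=bp_c.spec, B=1, members=[bp_c],
                              bootstrap_indices=[np.arange(t.n)])
        ens = TrainedEnsemble(bp_c=bp_c, b_bg=bag, voting="soft")
        np.testing.assert_array_equal(ens.predict_label(t.X),
                                      bp_c.predict_label(t.X))

    def test_hard_and_soft_agree_when_members_agree(self):
        ens_soft = TrainedEnsemble(bp_c=_StubLearner([0.9, 0.1]),
                                   b_bg=_StubLearner([0.7, 0.3]), voting="soft")
        ens_hard = TrainedEnsemble(bp_c=_StubLearner([0.9, 0.1]),
                                   b_bg=_StubLearner([0.7, 0.3]), voting="hard")
        X = np.zeros((2, 2))
        np.testing.assert_array_equal(ens_soft.predict_label(X),
                                      ens_hard.predict_label(X))

    def test_weighted_vote_uses_weights(self):
        ens = TrainedEnsemble(bp_c=_StubLearner([1.0, 0.0]),
                              b_bg=_StubLearner([0.0, 1.0]),
                              voting="weighted", weights=(3.0, 1.0))
        np.testing.assert_allclose(ens.predict_probability(np.zeros((1, 2))),
                                   [[0.75, 0.25]])

    def test_unknown_voting_rejected(self):
        t = separable_table()
        with pytest.raises(ValueError, match="voting"):
            fit_cbcec(t, voting="plurality")


class TestAblation:
    def test_degenerate_grid_matches_direct_fit(self, default_table):
        scaled = apply_minmax(fit_minmax(default_table), default_table)
        tr, te = make_splits(scaled, SplitPlan(train_fractions=(0.8,), seed=0))[0]
        grid = run_ablation(tr, te, estimators=("GB",), random_states=(10,),
                            voting_types=("soft",), B=5)
        direct = fit_cbcec(tr, B=5, voting="soft", seed=10, base_family="GB")
        acc = float(np.mean(direct.predict_label(te.X) == te.y))
        assert len(grid) == 1
        assert grid.loc[0, "accuracy"] == acc
        assert bool(grid.loc[0, "accepted"])

    def test_factorial_shape_and_determinism(self, default_table):
        scaled = apply_minmax(fit_minmax(default_table), default_table)
        tr, te = make_splits(scaled, SplitPlan(train_fractions=(0.8,), seed=0))[0]
        kwargs = dict(estimators=("DT", "ET"), random_states=(10, 25),
                      voting_types=("soft", "hard"),
                      feature_sets={"ALL": tr.feature_names,
                                    "SUB": tr.feature_names[:6]}, B=3)
        a = run_ablation(tr, te, **kwargs)
        b = run_ablation(tr, te, **kwargs)
        assert len(a) == 2 * 2 * 2 * 2
        assert (a["accuracy"] == b["accuracy"]).all()
        assert a["accepted"].any()

    def test_empty_grid_rejected(self, default_table):
        with pytest.raises(ValueError):
            run_ablation(default_table, default_table, estimators=())


def test_cbcec_no_harm_over_components():
    """Soft-voted hybrid is at least as good as its worse member, usually."""
    wins = 0
    n_seeds = 5  # the full 20-seed sweep runs in the acceptance suite
    for seed in range(n_seeds):
        t = generate(GeneratorConfig(seed=seed))
        scaled = apply_minmax(fit_minmax(t), t)
        tr, te = make_splits(scaled, SplitPlan(train_fractions=(0.8,), seed=seed))[0]
        ens = fit_cbcec(tr, seed=10)
        acc = lambda m: float(np.mean(m.predict_label(te.X) == te.y))
        wins += acc(ens) >= min(acc(ens.bp_c), acc(ens.b_bg))
    assert wins >= 4
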