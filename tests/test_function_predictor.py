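import itertools

import numpy as np
import pytest
from scipy.stats import binomtest

from chef.function_predictor import (
    FunctionPredictor,
    ModelConfig,
    evaluate,
    featurize,
    predict_profile,
    rank_molecules_for_label,
    split_train_test,
    train_model,
)
from chef.structure_coherence import fingerprint_molecules


class TestFeaturize:
    def test_shapes_and_order(self, small_dataset):
        X, Y = featurize(small_dataset, n_bits=512)
        assert X.shape == (small_dataset.n_molecules, 512)
        assert Y.shape == (small_dataset.n_molecules, small_dataset.n_labels)
        assert Y.sum() == small_dataset.n_pairs

    def test_label_free_molecule_keeps_zero_row(self, small_fixture):
        from chef.corpus_io import ChefDataset

        sets = [set() for _ in small_fixture.records]
        sets[1] = {"x"}
        ds = ChefDataset.from_label_sets(small_fixture.records, sets)
        _, Y = featurize(ds, n_bits=128)
        assert not Y[0].any() and Y[1].any()

    def test_duplicate_smiles_give_identical_rows(self):
        X = fingerprint_molecules(["c1ccccc1", "c1ccccc1"], n_bits=256)
        assert np.array_equal(X[0], X[1])


class TestSplit:
    def test_ten_percent_of_hundred(self):
        train, test = split_train_test(100, ModelConfig(test_fraction=0.1, seed=0))
        assert len(test) == 10 and len(train) == 90
        assert set(train) | set(test) == set(range(100))
        assert not set(train) & set(test)

    def test_same_seed_same_split(self):
        cfg = ModelConfig(seed=33)
        assert all(
            np.array_equal(a, b)
            for a, b in zip(split_train_test(57, cfg), split_train_test(57, cfg))
        )

    def test_two_molecules_half_split(self):
        train, test = split_train_test(2, ModelConfig(test_fraction=0.5))
        assert len(train) == len(test) == 1


def _separable_problem(rng, n=120, n_feat=32, n_labels=4):
    X = rng.random((n, n_feat)) < 0.3
    Y = X[:, :n_labels].copy()  # label j == feature j: linearly separable
    return X.astype(float), Y


class TestTraining:
    def test_perfectly_separable_labels_reach_auc_one(self, rng):
        X, Y = _separable_problem(rng)
        model = FunctionPredictor(model_kind="logistic", seed=0).fit(X[:100], Y[:100])
        ev = evaluate(model, X[100:], Y[100:])
        assert all(roc == 1.0 for roc, _, _ in ev.per_label.values())

    def test_structure_independent_label_stays_near_chance(self, rng):
        X = (rng.random((1000, 64)) < 0.3).astype(float)
        Y = (rng.random((1000, 1)) < 0.3)
        model = FunctionPredictor(model_kind="logistic", seed=0).fit(X[:500], Y[:500])
        ev = evaluate(model, X[500:], Y[500:])
        ((roc, _, _),) = ev.per_label.values()
        assert abs(roc - 0.5) < 0.1

    def test_untrainable_label_excluded_and_counted(self, rng):
        X, Y = _separable_problem(rng)
        Y = np.c_[Y, np.zeros(len(Y), dtype=bool)]  # label with no positives
        model = FunctionPredictor(model_kind="logistic", seed=0).fit(X, Y)
        assert not model.trainable_mask_[-1]
        ev = evaluate(model, X, Y)
        assert ev.n_labels_skipped >= 1
        assert str(Y.shape[1] - 1) not in ev.per_label

    @pytest.mark.parametrize("kind", ["logistic", "random_forest", "mlp"])
    def test_deterministic_given_seed_for_all_model_kinds(self, kind, rng):
        X, Y = _separable_problem(rng, n=80, n_feat=24)
        p1 = FunctionPredictor(model_kind=kind, seed=7).fit(X, Y).predict_proba(X)
        p2 = FunctionPredictor(model_kind=kind, seed=7).fit(X, Y).predict_proba(X)
        assert np.array_equal(p1, p2)
        assert np.all((p1 >= 0) & (p1 <= 1))

    def test_sklearn_param_interface(self):
        model = FunctionPredictor(model_kind="random_forest", seed=3)
        params = model.get_params()
        assert params["model_kind"] == "random_forest"
        clone = FunctionPredictor(**params)
        assert clone.get_params() == params


def _pairwise_auc_oracle(y, scores):
    wins = 0.0
    pairs = 0
    for i, j in itertools.product(range(len(y)), repeat=2):
        if y[i] == 1 and y[j] == 0:
            pairs += 1
            if scores[i] > scores[j]:
                wins += 1
            elif scores[i] == scores[j]:
                wins += 0.5
    return wins / pairs


class _FixedScores:
    """Stand-in model returning preset per-label scores."""

    def __init__(self, scores, labels):
        self._scores = np.asarray(scores, dtype=float)
        self.labels_ = list(labels)

    def predict_proba(self, X):
        return self._scores


class TestEvaluate:
    def test_worked_pairwise_example(self):
        y = np.array([[1], [0], [1], [0]], dtype=bool)
        scores = np.array([[0.9], [0.8], [0.4], [0.1]])
        ev = evaluate(_FixedScores(scores, ["lab"]), np.zeros((4, 2)), y)
        assert ev.per_label["lab"][0] == pytest.approx(0.75)
        assert _pairwise_auc_oracle(y[:, 0].astype(int), scores[:, 0]) == pytest.approx(0.75)

    def test_scores_equal_truth_give_perfect_metrics(self):
        y = np.array([[1], [0], [1]], dtype=bool)
        ev = evaluate(_FixedScores(y.astype(float), ["lab"]), np.zeros((3, 2)), y)
        assert ev.per_label["lab"][:2] == (1.0, 1.0)

    def test_constant_scores_give_half_auc(self):
        y = np.array([[1], [0], [1], [0]], dtype=bool)
        ev = evaluate(_FixedScores(np.full((4, 1), 0.3), ["lab"]), np.zeros((4, 2)), y)
        assert ev.per_label["lab"][0] == pytest.approx(0.5)

    def test_matches_pairwise_oracle_on_random_instances(self, rng):
        for _ in range(25):
            n = int(rng.integers(5, 50))
            y = np.zeros(n, dtype=bool)
            y[rng.choice(n, size=int(rng.integers(1, n)), replace=False)] = True
            if y.all():
                y[0] = False
            scores = np.round(rng.random(n), 1)  # coarse scores force ties
            ev = evaluate(_FixedScores(scores[:, None], ["lab"]), np.zeros((n, 2)), y[:, None])
            assert ev.per_label["lab"][0] == pytest.approx(
                _pairwise_auc_oracle(y.astype(int), scores)
            )

    def test_empty_test_set_rejected(self):
        with pytest.raises(ValueError):
            evaluate(_FixedScores(np.zeros((0, 1)), ["lab"]), np.zeros((0, 2)), np.zeros((0, 1), dtype=bool))


@pytest.fixture(scope="module")
def fitted(default_dataset, default_fps):
    Y = np.asarray(default_dataset.incidence.todense(), dtype=bool)
    return FunctionPredictor(model_kind="logistic", seed=0).fit(
        default_fps.astype(float), Y, label_names=default_dataset.vocabulary
    )


class TestRankingAndProfiles:
    def test_top_ranked_molecules_are_family_members(self, fitted, default_dataset, default_fps, default_fixture):
        fam0_label = sorted(default_fixture.family_labels[0])[0]
        ranked = rank_molecules_for_label(fitted, default_fps.astype(float), fam0_label, k=10)
        members = set(default_dataset.molecules_with_label(fam0_label))
        assert all(i in members for i, _ in ranked)

    def test_k_zero_and_k_beyond_pool(self, fitted, default_fps):
        assert rank_molecules_for_label(fitted, default_fps.astype(float), "antiviral", k=0) == []
        ranked = rank_molecules_for_label(fitted, default_fps.astype(float), "antiviral", k=10**6)
        assert len(ranked) == default_fps.shape[0]

    def test_unknown_label_raises(self, fitted, default_fps):
        with pytest.raises(KeyError):
            rank_molecules_for_label(fitted, default_fps.astype(float), "nope", k=5)

    def test_mean_member_rank_beats_random_over_seeds(self, default_dataset, default_fps):
        Y = np.asarray(default_dataset.incidence.todense(), dtype=bool)
        X = default_fps.astype(float)
        label = default_dataset.vocabulary[0]
        j = default_dataset.vocabulary.index(label)
        n = len(X)
        random_mean_rank = (n + 1) / 2
        wins = 0
        for seed in range(20):
            tr, te = split_train_test(n, ModelConfig(seed=seed))
            model = FunctionPredictor(model_kind="logistic", seed=seed).fit(
                X[tr], Y[tr], label_names=default_dataset.vocabulary
            )
            order = [i for i, _ in rank_molecules_for_label(model, X, label, k=n)]
            ranks = [order.index(i) + 1 for i in np.where(Y[:, j])[0]]
            wins += np.mean(ranks) < random_mean_rank
        assert binomtest(int(wins), 20, 0.5, alternative="greater").pvalue < 0.01

    def test_profile_for_family_member_ranks_family_label_top(self, fitted, default_dataset, default_fixture):
        i = 0
        profile = predict_profile(fitted, default_dataset.molecules[i].smiles)
        top = max(profile, key=profile.get)
        assert top in default_fixture.labels[i]

    def test_identical_inputs_identical_profiles(self, fitted):
        a = predict_profile(fitted, "c1ccc(-c2ccc(F)cc2)cc1")
        b = predict_profile(fitted, "Fc1ccc(-c2ccccc2)cc1")  # same molecule, different SMILES
        assert a == b
        assert all(0 <= v <= 1 for v in a.values())

    def test_malformed_smiles_rejected(self, fitted):
        with pytest.raises(ValueError):
            predict_profile(fitted, "not_a_smiles")


class TestTrainModelWrapper:
    def test_wrapper_uses_config(self, rng):
        X, Y = _separable_problem(rng, n=60)
        model = train_model(X, Y, ModelConfig(model_kind="random_forest", seed=1))
        assert model.model_kind == "random_forest"
        assert model.predict_proba(X).shape == Y.shape
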