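"""Ensemble: fold averaging, convex combination, simplex grid search, prediction."""

import numpy as np
import pytest

from genedrug import ensemble as ens
from genedrug import mlknn
from genedrug.data_model import ValidationError
from genedrug.druggability import score_all
from genedrug.features import FeatureKind, FeatureMatrix, build_feature_matrices
from genedrug.mlknn import ConfigurationError
from genedrug.synthetic_data import SimulationConfig, generate


def _models(n_models, seed=0, n=12, q=2):
    rng = np.random.default_rng(seed)
    return [
        mlknn.fit(rng.random((n, 3)), (rng.random((n, q)) < 0.4).astype(int), k=3)
        for _ in range(n_models)
    ]


class TestFeatureGroupScore:
    def test_identical_models_have_zero_sd(self):
        one = _models(1)[0]
        T = np.random.default_rng(1).random((4, 3))
        mean, sd = ens.feature_group_score([one] * 5, T)
        assert np.allclose(sd, 0.0)
        assert np.allclose(mean, one.predict_scores(T))

    def test_mean_and_sd_match_elementwise_recomputation(self):
        group = _models(5, seed=2)
        T = np.random.default_rng(3).random((4, 3))
        mean, sd = ens.feature_group_score(group, T)
        stack = np.stack([m.predict_scores(T) for m in group])
        assert np.allclose(mean, stack.mean(axis=0))
        assert np.allclose(sd, stack.std(axis=0))

    def test_wrong_group_size_rejected(self):
        with pytest.raises(ConfigurationError):
            ens.feature_group_score(_models(4), np.zeros((1, 3)))


class TestCombine:
    def test_identity_weighting_returns_first_matrix(self):
        rng = np.random.default_rng(0)
        mats = [rng.random((3, 4)) for _ in range(4)]
        out = ens.combine(mats, np.array([1.0, 0.0, 0.0, 0.0]))
        assert np.allclose(out, mats[0])

    def test_equal_weights_on_identical_matrices_are_idempotent(self):
        m = np.random.default_rng(1).random((3, 4))
        out = ens.combine([m, m, m, m], np.full(4, 0.25))
        assert np.allclose(out, m)

    def test_half_half_of_zero_and_one(self):
        z, o = np.zeros((2, 2)), np.ones((2, 2))
        assert np.allclose(ens.combine([z, o], np.array([0.5, 0.5])), 0.5)

    def test_simplex_violation_rejected(self):
        with pytest.raises(ValidationError):
            ens.combine([np.zeros((2, 2))] * 2, np.array([0.7, 0.6]))

    def test_combination_is_convex_cellwise(self):
        rng = np.random.default_rng(2)
        mats = [rng.random((5, 5)) for _ in range(4)]
        w = rng.dirichlet(np.ones(4))
        out = ens.combine(mats, w)
        stack = np.stack(mats)
        assert (out <= stack.max(axis=0) + 1e-12).all()
        assert (out >= stack.min(axis=0) - 1e-12).all()


def test_simplex_grid_combinatorics():
    assert len(ens.simplex_grid(2, 0.5)) == 3
    assert len(ens.simplex_grid(4, 0.1)) == 286
    for w in ens.simplex_grid(3, 0.25):
        assert sum(w) == pytest.approx(1.0)
        assert min(w) >= 0


class TestTuneWeights:
    def test_informative_feature_gets_largest_weight(self):
        # one feature carries the planted signal, three are pure noise
        rng = np.random.default_rng(42)
        ds, _ = generate(SimulationConfig(n_drugs=200, seed=42))
        mats = build_feature_matrices(ds, score_all(ds))
        noise = [
            FeatureMatrix(m.feature_kind, rng.random(m.values.shape)) for m in mats[1:]
        ]
        model = ens.tune_weights(
            [mats[0]] + noise,
            ens.label_matrix(ds),
            ens.eligible_mask(ds),
            k=10,
            grid_step=0.1,
            seed=0,
        )
        assert model.weights[0] == model.weights.max()
        assert model.weights[0] >= 0.4

    def test_identical_features_tie_break_to_uniform(self, small_synthetic):
        ds, _ = small_synthetic
        mats = build_feature_matrices(ds, score_all(ds))
        same = [FeatureMatrix(m.feature_kind, mats[0].values) for m in mats]
        model = ens.tune_weights(
            same, ens.label_matrix(ds), ens.eligible_mask(ds), k=5, grid_step=0.25, seed=0
        )
        assert np.allclose(model.weights, 0.25)

    def test_fewer_than_ten_drugs_rejected(self, minimal_ds):
        mats = build_feature_matrices(minimal_ds, score_all(minimal_ds))
        with pytest.raises(ValidationError):
            ens.tune_weights(
                mats, ens.label_matrix(minimal_ds), ens.eligible_mask(minimal_ds), k=2
            )

    def test_tuned_fitness_dominates_corner_predictors(self, small_synthetic):
        ds, _ = small_synthetic
        mats = build_feature_matrices(ds, score_all(ds))
        Y, mask = ens.label_matrix(ds), ens.eligible_mask(ds)
        model = ens.tune_weights(mats, Y, mask, k=5, grid_step=0.1, seed=7)
        rng = np.random.default_rng(7)
        folds = ens._stratified_folds(Y, 5, rng)
        oof, _ = ens.out_of_fold_scores(mats, Y, folds, k=5, s=1.0)
        from genedrug.metrics import pr_curve_aupr

        for f in range(4):
            corner = pr_curve_aupr(oof[f][mask], Y[mask])
            assert model.fitness >= corner - 1e-12

    def test_pipeline_reproducible_bit_for_bit(self, small_synthetic):
        ds, _ = small_synthetic
        a, mats_a = ens.train_on_dataset(ds, k=5, seed=13)
        b, _ = ens.train_on_dataset(ds, k=5, seed=13)
        assert (a.weights == b.weights).all()
        assert a.fitness == b.fitness
        pa = ens.predict(a, ds, feature_matrices=mats_a)
        pb = ens.predict(b, ds)
        assert pa == pb


@pytest.fixture(scope="module")
def trained(small_synthetic):
    ds, _ = small_synthetic
    model, mats = ens.train_on_dataset(ds, k=5, seed=1)
    return ds, model, mats


class TestPredict:

    def test_threshold_gates_calls(self, trained):
        ds, model, mats = trained
        none_called = ens.predict(model, ds, threshold=1.01, feature_matrices=mats)
        assert not any(call for *_, call in none_called)
        all_called = ens.predict(model, ds, threshold=0.0, feature_matrices=mats)
        assert all(call for *_, call in all_called)

    def test_only_eligible_pairs_reported_sorted_descending(self, trained):
        ds, model, mats = trained
        rows = ens.predict(model, ds, feature_matrices=mats)
        elig = ens.eligible_mask(ds)
        assert len(rows) == int(elig.sum())
        scores = [r[2] for r in rows]
        assert scores == sorted(scores, reverse=True)

    def test_calls_equal_independent_recombination(self, trained):
        ds, model, mats = trained
        rows = ens.predict(model, ds, threshold=0.5, feature_matrices=mats)
        per_fold = []
        for j in range(5):
            per_fold.append(
                ens.combine(
                    [model.base_predictors[f][j].predict_scores(mats[f].values) for f in range(4)],
                    model.weights,
                )
            )
        mean = np.stack(per_fold).mean(axis=0)
        dii = {d: i for i, d in enumerate(ds.drug_order)}
        dli = {d: l for l, d in enumerate(ds.diseases)}
        for drug, disease, score, _, call in rows:
            assert score == pytest.approx(mean[dii[drug], dli[disease]])
            assert call == (score >= 0.5)

    def test_ensemble_artifact_roundtrip(self, trained, tmp_path):
        ds, model, mats = trained
        model.save(tmp_path / "ens.json")
        loaded = ens.EnsembleModel.load(tmp_path / "ens.json")
        assert ens.predict(loaded, ds, feature_matrices=mats) == ens.predict(
            model, ds, feature_matrices=mats
        )
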