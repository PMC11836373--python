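"""Hyperparameter tuning and wrapper feature selection tests."""

import itertools

import numpy as np
import pytest

from acovit.aco import ACOConfig
from acovit.synthetic import informative_features
from acovit.tuning import (
    FeatureSelectionResult,
    HyperparamSpace,
    TrainEvalResult,
    hyperparam_fitness,
    model_complexity,
    select_features_aco,
    tune,
)


class TestComplexityAndFitness:
    def test_normalized_dense_width(self):
        space = HyperparamSpace()
        assert model_complexity({"dense_neurons": 1024}, space) == 1.0
        assert model_complexity({"dense_neurons": 512}, space) == 0.5

    def test_fitness_is_loss_plus_scaled_complexity(self):
        space = HyperparamSpace()
        fn = lambda cfg: TrainEvalResult(0.5, 0.8, 3)  # noqa: E731
        cfg = {"learning_rate": 0.01, "batch_size": 32, "dense_neurons": 512}
        assert hyperparam_fitness(cfg, fn, 0.0, space) == pytest.approx(0.5)
        assert hyperparam_fitness(cfg, fn, 1.0, space) == pytest.approx(1.0)

    def test_fitness_monotone_in_lambda(self):
        space = HyperparamSpace()
        fn = lambda cfg: TrainEvalResult(0.3, 0.9, 3)  # noqa: E731
        cfg = {"learning_rate": 0.1, "batch_size": 16, "dense_neurons": 256}
        vals = [hyperparam_fitness(cfg, fn, lam, space) for lam in (0.0, 0.5, 1.0)]
        assert vals == sorted(vals)

    def test_initial_values_must_be_grid_members(self):
        with pytest.raises(ValueError):
            HyperparamSpace(learning_rate=(0.1,), initial={
                "learning_rate": 0.05, "batch_size": 32, "dense_neurons": 512,
            })


class TestTune:
    @staticmethod
    def stub_table(space):
        best = (0.001, 32, 256)
        table = {}
        for lr, bs, dn in itertools.product(
            space.learning_rate, space.batch_size, space.dense_neurons
        ):
            dist = (
                abs(np.log10(lr) - np.log10(best[0]))
                + abs(bs - best[1]) / 64
                + abs(dn - best[2]) / 1024
            )
            table[(lr, bs, dn)] = 0.1 + dist
        return table, best

    def test_unique_best_config_found_on_full_grid(self):
        space = HyperparamSpace()
        table, best = self.stub_table(space)
        hits = 0
        for seed in range(20):
            fn = lambda c: TrainEvalResult(  # noqa: E731
                table[(c["learning_rate"], c["batch_size"], c["dense_neurons"])],
                0.5, 3,
            )
            cfg, _ = tune(space, fn, lam=0.0,
                          aco_config=ACOConfig(seed=seed, max_iterations=30,
                                               patience=30))
            hits += (cfg["learning_rate"], cfg["batch_size"],
                     cfg["dense_neurons"]) == best
        assert hits >= 19

    def test_constant_stub_flat_trace(self):
        space = HyperparamSpace()
        fn = lambda c: TrainEvalResult(0.7, 0.5, 3)  # noqa: E731
        cfg, trace = tune(space, fn, lam=0.0, aco_config=ACOConfig(seed=0))
        assert len(set(trace.best_so_far)) == 1
        assert cfg["learning_rate"] in space.learning_rate
        assert cfg["batch_size"] in space.batch_size
        assert cfg["dense_neurons"] in space.dense_neurons

    def test_returned_fitness_is_minimum_of_all_evaluated(self):
        space = HyperparamSpace()
        seen = []

        def fn(c):
            loss = 0.1 * c["dense_neurons"] / 1024 + c["learning_rate"]
            seen.append(loss)
            return TrainEvalResult(loss, 0.5, 3)

        cfg, trace = tune(space, fn, lam=0.0, aco_config=ACOConfig(seed=3))
        assert trace.best_so_far[-1] == pytest.approx(min(seen))


class TestFeatureSelection:
    def test_informative_features_recovered(self):
        rng = np.random.default_rng(0)
        X, y, truth = informative_features(120, 12, 3, rng)
        res = select_features_aco(
            X, y, lam=0.02,
            aco_config=ACOConfig(seed=0, n_ants=12, max_iterations=25, patience=25),
        )
        assert (res.mask & truth).sum() >= 2

    def test_huge_lambda_shrinks_to_single_best_feature(self):
        rng = np.random.default_rng(1)
        X, y, _ = informative_features(60, 3, 1, rng)
        res = select_features_aco(
            X, y, lam=50.0,
            aco_config=ACOConfig(seed=1, n_ants=10, max_iterations=30, patience=30),
        )
        assert res.mask.sum() == 1
        assert res.mask[0]  # the only informative column wins

    def test_single_feature_forced_inclusion(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(40, 1))
        y = (X[:, 0] > 0).astype(int)
        res = select_features_aco(X, y, lam=0.0,
                                  aco_config=ACOConfig(seed=0, max_iterations=5,
                                                       patience=5))
        assert res.mask.tolist() == [True]

    def test_deterministic_per_seed(self):
        rng = np.random.default_rng(3)
        X, y, _ = informative_features(80, 8, 2, rng)
        cfg = ACOConfig(seed=9, n_ants=8, max_iterations=10, patience=10)
        a = select_features_aco(X, y, 0.02, cfg)
        b = select_features_aco(X, y, 0.02, cfg)
        np.testing.assert_array_equal(a.mask, b.mask)
        assert a.fitness == b.fitness

    def test_degenerate_labels_rejected(self):
        with pytest.raises(ValueError, match="single class"):
            select_features_aco(np.zeros((20, 3)), np.zeros(20, int), 0.0)

    def test_empty_mask_type_invalid(self):
        with pytest.raises(ValueError):
            FeatureSelectionResult(np.zeros(4, bool), 0.0, None)
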