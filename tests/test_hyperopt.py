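import numpy as np
import pytest

from oxispec import hyperopt as hp
from oxispec import model as M


def quadratic_objective(config):
    """1-D synthetic objective over the learning rate with a single interior
    optimum on the log scale (peak at 3e-3)."""
    x = np.log10(config["learning_rate"])
    return [float(1.0 - (x + 2.5) ** 2 / 10.0)]


class TestSearchSpace:
    def test_grid_default_reproduces_published_lists(self):
        space = hp.SearchSpace.grid_default()
        assert space.values["filters_block1"] == [2, 4, 8, 16, 32, 64]
        assert space.values["kernel_size"] == [2, 4, 8, 16, 32]
        assert space.values["learning_rate"] == [1e-4, 1e-3, 1e-2, 0.1]
        assert space.values["epochs"] == [10, 50, 100, 200, 300, 400, 500]
        assert space.values["dropout_ratio"] == pytest.approx(
            [0.1, 0.2, 0.3, 0.4, 0.5, 0.6, 0.7, 0.8, 0.9, 1.0]
        )
        assert space.values["dense_nodes"] == list(range(10, 101, 10))
        assert space.values["batch_size"] == [10, 50, 100, 200, 300]
        assert space.values["n_dense_layers"] == [2, 4, 6, 8, 10]

    def test_bounds_default_reproduces_published_ranges(self):
        space = hp.SearchSpace.bounds_default()
        assert space.bounds["filters_block1"] == (2, 64, "int")
        assert space.bounds["learning_rate"] == (1e-4, 0.1, "log-real")
        assert space.bounds["dropout_ratio"] == (0.01, 1.0, "real")
        assert space.bounds["epochs"] == (10, 500, "int")

    def test_exactly_one_mode(self):
        with pytest.raises(ValueError):
            hp.SearchSpace()
        with pytest.raises(ValueError):
            hp.SearchSpace(values={"a": [1]}, bounds={"b": (0, 1, "real")})

    def test_full_grid_is_refused(self):
        space = hp.SearchSpace.grid_default()
        with pytest.raises(ValueError, match="cap"):
            hp.grid_search(space, objective=quadratic_objective)


class TestGridSearch:
    def test_single_point_space_returns_it(self):
        space = hp.SearchSpace(values={"learning_rate": [1e-3]})
        res = hp.grid_search(space, objective=quadratic_objective)
        assert res.best_config == {"learning_rate": 1e-3}
        assert len(res.trials) == 1

    def test_best_score_is_max_of_trials(self):
        space = hp.SearchSpace(values={"learning_rate": [1e-4, 1e-3, 1e-2, 0.1]})
        res = hp.grid_search(space, objective=quadratic_objective)
        assert res.best_score == max(t.mean_score for t in res.trials)
        assert res.best_config["learning_rate"] == 1e-3  # closest to the peak

    def test_properly_trained_config_beats_degenerate(self, second_dataset):
        # epochs=10 at a vanishing learning rate cannot learn; the properly
        # trained point must win the 2-point grid
        base = M.best_reported_config(epochs=20, seed=0)
        space = hp.SearchSpace(values={"learning_rate": [1e-4, 9e-4], "epochs": [20]})

        def objective(config):
            cfg = base.with_(**config)
            if config["learning_rate"] < 5e-4:
                cfg = cfg.with_(epochs=10)  # degenerate short training
            from oxispec.hyperopt import cv_objective

            return cv_objective(second_dataset, k_folds=2, base_config=cfg, seed=0)(
                {k: v for k, v in config.items() if k != "epochs"}
            )

        res = hp.grid_search(space, objective=objective)
        assert res.best_config["learning_rate"] == 9e-4


class TestBayesOpt:
    def test_finds_top_decile_of_brute_force_grid(self):
        space = hp.SearchSpace(bounds={"learning_rate": (1e-4, 0.1, "log-real")})
        res = hp.bayes_opt(space, n_trials=25, seed=0, objective=quadratic_objective)
        # brute-force oracle over a dense grid of the same objective
        grid = np.logspace(-4, -1, 1000)
        scores = np.array([quadratic_objective({"learning_rate": lr})[0] for lr in grid])
        decile = np.quantile(scores, 0.9)
        assert res.best_score >= decile

    def test_all_proposals_respect_bounds(self):
        space = hp.SearchSpace(
            bounds={"learning_rate": (1e-4, 0.1, "log-real"), "dense_nodes": (1, 100, "int")}
        )

        def objective(config):
            return [float(np.sin(config["dense_nodes"]) + np.log10(config["learning_rate"]))]

        res = hp.bayes_opt(space, n_trials=12, seed=1, objective=objective)
        for t in res.trials:
            assert space.contains(t.config)
            assert isinstance(t.config["dense_nodes"], int)

    def test_different_seeds_both_respect_bounds(self):
        space = hp.SearchSpace(bounds={"learning_rate": (1e-4, 0.1, "log-real")})
        r1 = hp.bayes_opt(space, n_trials=8, seed=1, objective=quadratic_objective)
        r2 = hp.bayes_opt(space, n_trials=8, seed=2, objective=quadratic_objective)
        assert all(space.contains(t.config) for t in r1.trials + r2.trials)
        seq1 = [t.config["learning_rate"] for t in r1.trials]
        seq2 = [t.config["learning_rate"] for t in r2.trials]
        assert seq1 != seq2  # stochastic proposal sequence

    def test_deterministic_under_seed(self):
        space = hp.SearchSpace(bounds={"learning_rate": (1e-4, 0.1, "log-real")})
        r1 = hp.bayes_opt(space, n_trials=10, seed=3, objective=quadratic_objective)
        r2 = hp.bayes_opt(space, n_trials=10, seed=3, objective=quadratic_objective)
        assert [t.config for t in r1.trials] == [t.config for t in r2.trials]

    def test_too_few_trials_rejected(self):
        space = hp.SearchSpace(bounds={"learning_rate": (1e-4, 0.1, "log-real")})
        with pytest.raises(ValueError):
            hp.bayes_opt(space, n_trials=3, objective=quadratic_objective)


class TestCoarseThenFine:
    def test_stage2_bounds_nested_and_result_monotone(self):
        space = hp.SearchSpace(bounds={"learning_rate": (1e-4, 0.1, "log-real")})
        stage1 = hp.bayes_opt(space, n_trials=10, seed=0, objective=quadratic_objective)
        two_stage = hp.coarse_then_fine(
            space, stage2_shrink=0.25, seed=0, n_trials=20, objective=quadratic_objective
        )
        # pooled trials can only improve on stage 1 (same seed, same stage-1 run)
        assert two_stage.best_score >= stage1.best_score
        fine = hp._shrunk_space(space, stage1.best_config, 0.25)
        lo, hi, _ = fine.bounds["learning_rate"]
        assert 1e-4 <= lo < hi <= 0.1

    def test_trials_are_concatenated(self):
        space = hp.SearchSpace(bounds={"learning_rate": (1e-4, 0.1, "log-real")})
        res = hp.coarse_then_fine(
            space, stage2_shrink=0.3, seed=4, n_trials=16, objective=quadratic_objective
        )
        assert len(res.trials) >= 16
        assert res.best_score == max(t.mean_score for t in res.trials)
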