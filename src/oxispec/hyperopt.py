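"""Hyperparameter search: exhaustive grid with cross-validation, and
sequential Bayesian optimization with a Gaussian-process surrogate.

Two search modes mirror the two published searching-condition tables:

* grid mode — every hyperparameter carries an explicit value list; each
  combination is scored by stratified k-fold cross-validation accuracy and
  the best point is refit on the full training set.  The full product space
  is combinatorially huge, so the searcher refuses grids above a cap and
  the caller pins all but a few axes (one-axis-at-a-time usage).
* interval mode — bounded continuous/integer ranges; a Matern Gaussian
  process models the cross-validation score over the hyperparameters
  (scaled to the unit cube, log-scaled for the learning rate) and expected
  improvement proposes each next trial.  Integer parameters are proposed by
  rounding.

A two-stage coarse-then-fine wrapper re-centers a shrunken search space on
the stage-1 optimum and continues there.
"""

from __future__ import annotations

import itertools
import math
import time
from dataclasses import dataclass, field, replace
from typing import Callable, Literal

import numpy as np
from scipy.stats import norm
from sklearn.gaussian_process import GaussianProcessRegressor
from sklearn.gaussian_process.kernels import ConstantKernel, Matern, WhiteKernel
from sklearn.model_selection import StratifiedKFold

from . import model as model_mod
from .preprocess import LabeledDataset

__all__ = [
    "SearchSpace",
    "TrialRecord",
    "SearchResult",
    "GRID_TABLE",
    "BOUNDS_TABLE",
    "grid_search",
    "bayes_opt",
    "coarse_then_fine",
    "cv_objective",
]

#: Published grid-search value lists.
GRID_TABLE: dict[str, list] = {
    "filters_block1": [2, 4, 8, 16, 32, 64],
    "filters_block2": [2, 4, 8, 16, 32, 64],
    "n_dense_layers": [2, 4, 6, 8, 10],
    "kernel_size": [2, 4, 8, 16, 32],
    "dropout_ratio": [round(0.1 * i, 1) for i in range(1, 11)],
    "dense_nodes": list(range(10, 101, 10)),
    "learning_rate": [1e-4, 1e-3, 1e-2, 0.1],
    "batch_size": [10, 50, 100, 200, 300],
    "epochs": [10, 50, 100, 200, 300, 400, 500],
}

#: Published interval bounds (param: (low, high, kind)); the learning rate
#: is searched on a log scale.
BOUNDS_TABLE: dict[str, tuple[float, float, str]] = {
    "filters_block1": (2, 64, "int"),
    "filters_block2": (2, 64, "int"),
    "n_dense_layers": (1, 10, "int"),
    "kernel_size": (2, 32, "int"),
    "dropout_ratio": (0.01, 1.0, "real"),
    "dense_nodes": (1, 100, "int"),
    "learning_rate": (1e-4, 0.1, "log-real"),
    "batch_size": (10, 300, "int"),
    "epochs": (10, 500, "int"),
}


@dataclass(frozen=True)
class SearchSpace:
    """Either an explicit grid (``values``) or bounded intervals (``bounds``).

    Exactly one of the two is set.  ``SearchSpace.grid_default()`` and
    ``SearchSpace.bounds_default()`` reproduce the published tables.
    """

    values: dict[str, list] | None = None
    bounds: dict[str, tuple[float, float, str]] | None = None

    def __post_init__(self):
        if (self.values is None) == (self.bounds is None):
            raise ValueError("specify exactly one of values (grid) or bounds (interval)")
        if self.values is not None:
            for k, v in self.values.items():
                if not v:
                    raise ValueError(f"empty value list for {k}")
        else:
            for k, (lo, hi, kind) in self.bounds.items():
                if not lo < hi:
                    raise ValueError(f"bounds for {k} need low < high")
                if kind not in ("int", "real", "log-real"):
                    raise ValueError(f"unknown bound kind {kind!r} for {k}")

    @property
    def mode(self) -> Literal["grid", "interval"]:
        return "grid" if self.values is not None else "interval"

    @classmethod
    def grid_default(cls, **pinned) -> "SearchSpace":
        """The full published grid, with any axis pinned to a single value."""
        values = {k: list(v) for k, v in GRID_TABLE.items()}
        for k, v in pinned.items():
            values[k] = list(v) if isinstance(v, (list, tuple)) else [v]
        return cls(values=values)

    @classmethod
    def bounds_default(cls, subset: list[str] | None = None) -> "SearchSpace":
        """The published interval space, optionally restricted to some axes."""
        b = dict(BOUNDS_TABLE)
        if subset is not None:
            b = {k: b[k] for k in subset}
        return cls(bounds=b)

    def n_grid_points(self) -> int:
        if self.mode != "grid":
            raise ValueError("not a grid space")
        return math.prod(len(v) for v in self.values.values())

    def contains(self, config: dict) -> bool:
        if self.mode == "grid":
            return all(config[k] in v for k, v in self.values.items())
        return all(lo <= config[k] <= hi for k, (lo, hi, _) in self.bounds.items())


@dataclass
class TrialRecord:
    config: dict
    cv_scores: list[float]
    mean_score: float
    wall_time_s: float
    seed: int

    def __post_init__(self):
        if self.cv_scores and abs(self.mean_score - float(np.mean(self.cv_scores))) > 1e-9:
            raise ValueError("mean_score must equal mean(cv_scores)")


@dataclass
class SearchResult:
    best_config: dict
    best_score: float
    trials: list[TrialRecord]
    refit_model: "model_mod.TrainedModel | None" = None

    def __post_init__(self):
        if self.trials:
            top = max(t.mean_score for t in self.trials)
            if abs(self.best_score - top) > 1e-12:
                raise ValueError("best_score must be the max over trials")


def cv_objective(
    dataset: LabeledDataset,
    k_folds: int = 5,
    base_config: "model_mod.CNNConfig | None" = None,
    seed: int = 0,
) -> Callable[[dict], list[float]]:
    """Per-fold CV accuracy of the classifier under a hyperparameter dict.

    Returned callable maps a config dict (subset of CNNConfig fields) to the
    list of fold accuracies.  Fold assignment is stratified and fixed by
    ``seed`` so all trials see identical folds.
    """
    base = base_config or model_mod.CNNConfig()
    width = dataset.X.shape[1]
    n_classes = len(dataset.label_vector)
    skf = StratifiedKFold(n_splits=k_folds, shuffle=True, random_state=seed % (2**31))
    folds = list(skf.split(dataset.X, dataset.y))

    def objective(config: dict) -> list[float]:
        cfg = base.with_(seed=seed, **config)
        scores = []
        for tr_idx, va_idx in folds:
            sub = LabeledDataset(
                X=dataset.X[tr_idx],
                y=dataset.y[tr_idx],
                region=dataset.region,
                label_vector=dataset.label_vector,
                noise_ratio=dataset.noise_ratio,
                seed=dataset.seed,
            )
            net = model_mod.build_model(cfg, width, n_classes)
            tm = model_mod.train(net, sub, cfg)
            pred = model_mod.predict_batch(tm, dataset.X[va_idx]).argmax(axis=1)
            truth = np.searchsorted(np.asarray(dataset.label_vector, float), dataset.y[va_idx])
            scores.append(float(np.mean(pred == truth)))
        return scores

    return objective


def _refit(dataset: LabeledDataset, config: dict, base, seed: int):
    cfg = (base or model_mod.CNNConfig()).with_(seed=seed, **config)
    net = model_mod.build_model(cfg, dataset.X.shape[1], len(dataset.label_vector))
    return model_mod.train(net, dataset, cfg)


def grid_search(
    space: SearchSpace,
    dataset: LabeledDataset | None = None,
    k_folds: int = 5,
    seed: int = 0,
    objective: Callable[[dict], list[float]] | None = None,
    grid_cap: int = 256,
    base_config: "model_mod.CNNConfig | None" = None,
    refit: bool = True,
) -> SearchResult:
    """Exhaustively score every grid point; ties keep the first point in
    lexicographic grid order; the best config is refit on the full set."""
    if space.mode != "grid":
        raise ValueError("grid_search needs a grid-mode space")
    n = space.n_grid_points()
    if n > grid_cap:
        raise ValueError(
            f"grid has {n} points, above the cap of {grid_cap}; pin more axes "
            "(the full published grid is not exhaustively searchable)"
        )
    if objective is None:
        if dataset is None:
            raise ValueError("need a dataset or an explicit objective")
        objective = cv_objective(dataset, k_folds, base_config, seed)

    names = sorted(space.values)
    trials: list[TrialRecord] = []
    best: TrialRecord | None = None
    for combo in itertools.product(*(space.values[k] for k in names)):
        config = dict(zip(names, combo))
        t0 = time.perf_counter()
        scores = objective(config)
        rec = TrialRecord(
            config=config,
            cv_scores=list(scores),
            mean_score=float(np.mean(scores)),
            wall_time_s=time.perf_counter() - t0,
            seed=seed,
        )
        trials.append(rec)
        if best is None or rec.mean_score > best.mean_score:
            best = rec
    refit_model = _refit(dataset, best.config, base_config, seed) if (refit and dataset is not None) else None
    return SearchResult(best.config, best.mean_score, trials, refit_model)


# ------------------------------------------------------- bayesian search ---


def _to_unit(space: SearchSpace, config: dict) -> np.ndarray:
    out = []
    for k in sorted(space.bounds):
        lo, hi, kind = space.bounds[k]
        v = config[k]
        if kind == "log-real":
            out.append((np.log(v) - np.log(lo)) / (np.log(hi) - np.log(lo)))
        else:
            out.append((v - lo) / (hi - lo))
    return np.array(out)


def _from_unit(space: SearchSpace, u: np.ndarray) -> dict:
    config = {}
    for x, k in zip(u, sorted(space.bounds)):
        lo, hi, kind = space.bounds[k]
        if kind == "log-real":
            v = float(np.exp(np.log(lo) + x * (np.log(hi) - np.log(lo))))
        else:
            v = float(lo + x * (hi - lo))
        if kind == "int":
            v = int(np.clip(round(v), lo, hi))
        config[k] = v
    return config


def bayes_opt(
    space: SearchSpace,
    dataset: LabeledDataset | None = None,
    n_trials: int = 25,
    seed: int = 0,
    objective: Callable[[dict], list[float]] | None = None,
    k_folds: int = 5,
    n_init: int = 5,
    base_config: "model_mod.CNNConfig | None" = None,
    refit: bool = True,
) -> SearchResult:
    """Sequential GP-surrogate search with expected-improvement proposals.

    The first ``n_init`` trials are space-filling random draws; afterwards a
    Matern(5/2) Gaussian process fit to all (config, score) pairs scores 512
    random candidates by expected improvement and the best is evaluated.
    Deterministic trial sequence under ``seed``.
    """
    if space.mode != "interval":
        raise ValueError("bayes_opt needs an interval-mode space")
    if n_trials < 5:
        raise ValueError("n_trials must be at least 5")
    if objective is None:
        if dataset is None:
            raise ValueError("need a dataset or an explicit objective")
        objective = cv_objective(dataset, k_folds, base_config, seed)

    rng = np.random.default_rng(seed)
    dim = len(space.bounds)
    X_obs: list[np.ndarray] = []
    y_obs: list[float] = []
    trials: list[TrialRecord] = []
    failures: list[tuple[dict, str]] = []

    def evaluate(u: np.ndarray):
        config = _from_unit(space, u)
        t0 = time.perf_counter()
        try:
            scores = objective(config)
        except (FloatingPointError, ValueError) as e:
            failures.append((config, str(e)))
            return
        rec = TrialRecord(
            config=config,
            cv_scores=list(scores),
            mean_score=float(np.mean(scores)),
            wall_time_s=time.perf_counter() - t0,
            seed=seed,
        )
        trials.append(rec)
        X_obs.append(_to_unit(space, config))
        y_obs.append(rec.mean_score)

    for _ in range(min(n_init, n_trials)):
        evaluate(rng.random(dim))

    kernel = ConstantKernel(1.0) * Matern(length_scale=0.3 * np.ones(dim), nu=2.5) + WhiteKernel(1e-4)
    while len(trials) + len(failures) < n_trials:
        if len(X_obs) < 2:
            evaluate(rng.random(dim))
            continue
        gp = GaussianProcessRegressor(kernel=kernel, normalize_y=True, random_state=seed % (2**31))
        gp.fit(np.vstack(X_obs), np.asarray(y_obs))
        cand = rng.random((512, dim))
        mu, sd = gp.predict(cand, return_std=True)
        best_y = max(y_obs)
        xi = 1e-3
        z = np.where(sd > 0, (mu - best_y - xi) / np.maximum(sd, 1e-12), 0.0)
        ei = (mu - best_y - xi) * norm.cdf(z) + sd * norm.pdf(z)
        ei[sd == 0] = 0.0
        evaluate(cand[int(np.argmax(ei))])

    if not trials:
        raise RuntimeError(f"all {len(failures)} trials failed: {failures[:3]}")
    best = max(trials, key=lambda t: t.mean_score)
    refit_model = _refit(dataset, best.config, base_config, seed) if (refit and dataset is not None) else None
    return SearchResult(best.config, best.mean_score, trials, refit_model)


def _shrunk_space(space: SearchSpace, center: dict, shrink: float) -> SearchSpace:
    """Interval space of width ``shrink``·original, re-centered and clipped."""
    if space.mode == "interval":
        src = space.bounds
    else:
        src = {
            k: (min(v), max(v), "real" if isinstance(v[0], float) else "int")
            for k, v in space.values.items()
        }
    new_bounds = {}
    for k, (lo, hi, kind) in src.items():
        c = center[k]
        if kind == "log-real":
            llo, lhi = np.log(lo), np.log(hi)
            half = 0.5 * shrink * (lhi - llo)
            lc = np.clip(np.log(c), llo + half, lhi - half)
            nlo, nhi = float(np.exp(lc - half)), float(np.exp(lc + half))
        else:
            half = 0.5 * shrink * (hi - lo)
            c = float(np.clip(c, lo + half, hi - half))
            nlo, nhi = c - half, c + half
            if kind == "int":
                nlo, nhi = math.floor(nlo), math.ceil(nhi)
                nhi = max(nhi, nlo + 1)
        new_bounds[k] = (nlo, nhi, kind)
    return SearchSpace(bounds=new_bounds)


def coarse_then_fine(
    space: SearchSpace,
    dataset: LabeledDataset | None = None,
    stage2_shrink: float = 0.25,
    seed: int = 0,
    n_trials: int = 25,
    objective: Callable[[dict], list[float]] | None = None,
    k_folds: int = 5,
    base_config: "model_mod.CNNConfig | None" = None,
    refit: bool = True,
    grid_cap: int = 256,
) -> SearchResult:
    """Stage 1 over the full space, stage 2 over a shrunken interval around
    the stage-1 best; the pooled trials can only improve on stage 1."""
    if not 0 < stage2_shrink < 1:
        raise ValueError("stage2_shrink must be in (0, 1)")
    n1 = max(n_trials // 2, 5) if space.mode == "interval" else n_trials
    if space.mode == "interval":
        stage1 = bayes_opt(
            space, dataset, n1, seed, objective, k_folds, base_config=base_config, refit=False
        )
    else:
        stage1 = grid_search(
            space, dataset, k_folds, seed, objective, grid_cap, base_config, refit=False
        )
    fine = _shrunk_space(space, stage1.best_config, stage2_shrink)
    n2 = max(n_trials - len(stage1.trials), 5)
    stage2 = bayes_opt(
        fine, dataset, n2, seed + 1, objective, k_folds, base_config=base_config, refit=False
    )
    trials = stage1.trials + stage2.trials
    best = max(trials, key=lambda t: t.mean_score)
    refit_model = _refit(dataset, best.config, base_config, seed) if (refit and dataset is not None) else None
    return SearchResult(best.config, best.mean_score, trials, refit_model)
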