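"""Metrics and study harness: classification accuracy, per-concentration
deviation tables, calibration regression, and the region x noise ablation.

Two kinds of "accuracy" coexist here and both are reported: argmax
classification accuracy against the 10-label grid, and tolerance-band
accuracy of the expectation-decoded scalar (a decoded estimate within
+/-1 % of the truth counts as correct).  Deviation tables summarise the
decoded estimates per concentration (max / mean / std of the absolute
error); the total relative error is the mean absolute relative error in
percent over all rows.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from sklearn.model_selection import train_test_split

from . import model as model_mod
from .preprocess import DEFAULT_LABELS, NOISE_RATIOS, REGIONS, LabeledDataset, RegionSpec, build_dataset
from .simulator import SimulatorConfig, SpectralFrame, default_config, simulate_frame

__all__ = [
    "DeviationReport",
    "CalibrationFit",
    "AblationReport",
    "accuracy",
    "tolerance_accuracy",
    "deviation_report",
    "calibration_fit",
    "run_ablation",
    "train_test_datasets",
]


def accuracy(model: "model_mod.TrainedModel", test: LabeledDataset) -> float:
    """Fraction of rows whose argmax class matches the true label."""
    if len(test) == 0:
        raise ValueError("empty test set")
    if test.X.shape[1] != model.input_length:
        raise ValueError("test region width does not match the model")
    P = model_mod.predict_batch(model, test.X)
    pred = np.asarray(model.label_vector, dtype=float)[P.argmax(axis=1)]
    return float(np.mean(pred == test.y))


def tolerance_accuracy(model: "model_mod.TrainedModel", test: LabeledDataset, tol: float = 1.0) -> float:
    """Fraction of rows whose expectation-decoded SpO2 is within ``tol`` percent."""
    if len(test) == 0:
        raise ValueError("empty test set")
    decoded = model_mod.decode_batch(model, test.X)
    return float(np.mean(np.abs(decoded - test.y) <= tol))


@dataclass
class DeviationReport:
    """Per-concentration deviation of decoded estimates, plus the pooled
    mean absolute relative error in percent."""

    rows: pd.DataFrame  # label, max_abs_deviation, mean_abs_deviation, std_deviation
    total_relative_error: float

    def __str__(self) -> str:
        lines = [f"{'SpO2 (%)':>9} {'max dev':>8} {'mean dev':>9} {'std':>7}"]
        for _, r in self.rows.iterrows():
            lines.append(
                f"{r['label']:>9.0f} {r['max_abs_deviation']:>8.2f} "
                f"{r['mean_abs_deviation']:>9.2f} {r['std_deviation']:>7.2f}"
            )
        lines.append(f"Total relative error: {self.total_relative_error:.2f}%")
        return "\n".join(lines)


def deviation_report(
    decoded: np.ndarray,
    truth: np.ndarray,
    labels: Sequence[float] | None = None,
    std: Literal["population", "sample"] = "population",
) -> DeviationReport:
    """Group absolute deviations |decoded - truth| by true concentration."""
    decoded = np.asarray(decoded, dtype=float)
    truth = np.asarray(truth, dtype=float)
    if decoded.shape != truth.shape:
        raise ValueError("decoded and truth must have equal length")
    wanted = sorted(set(truth)) if labels is None else list(labels)
    rows = []
    for lab in wanted:
        sel = truth == lab
        if not sel.any():
            warnings.warn(f"label {lab} absent from truth; row omitted", stacklevel=2)
            continue
        dev = np.abs(decoded[sel] - truth[sel])
        rows.append(
            {
                "label": lab,
                "max_abs_deviation": float(dev.max()),
                "mean_abs_deviation": float(dev.mean()),
                "std_deviation": float(dev.std(ddof=0 if std == "population" else 1)),
            }
        )
    total = float(np.mean(np.abs(decoded - truth) / truth) * 100.0)
    return DeviationReport(rows=pd.DataFrame(rows), total_relative_error=total)


@dataclass(frozen=True)
class CalibrationFit:
    """Ordinary least squares of predicted on reference values."""

    slope: float
    intercept: float
    r_squared: float

    def __post_init__(self):
        if not 0.0 <= self.r_squared <= 1.0 + 1e-12:
            raise ValueError("r_squared must lie in [0, 1]")


def calibration_fit(predicted: np.ndarray, reference: np.ndarray) -> CalibrationFit:
    """Fit predicted ~ slope * reference + intercept; R^2 = 1 - SSres/SStot."""
    predicted = np.asarray(predicted, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if predicted.size < 3 or predicted.shape != reference.shape:
        raise ValueError("need at least 3 paired points")
    if np.ptp(reference) == 0:
        raise ValueError("reference values are constant; calibration fit is degenerate")
    slope, intercept = np.polyfit(reference, predicted, 1)
    fitted = slope * reference + intercept
    ss_res = float(np.sum((predicted - fitted) ** 2))
    ss_tot = float(np.sum((predicted - predicted.mean()) ** 2))
    r2 = 1.0 if ss_tot == 0 else 1.0 - ss_res / ss_tot
    return CalibrationFit(slope=float(slope), intercept=float(intercept), r_squared=float(max(r2, 0.0)))


def train_test_datasets(
    region: RegionSpec,
    noise_ratio_train: float,
    noise_ratio_test: float,
    seed: int,
    n_rows_train: int = 200,
    n_rows_test: int = 50,
    sim_config: SimulatorConfig | None = None,
    labels: Sequence[int] = DEFAULT_LABELS,
) -> tuple[LabeledDataset, LabeledDataset]:
    """Training and verification datasets from two independent simulated
    measurement sessions (separate sensor-noise realizations)."""
    seed = int(seed) % (2**20)
    cfg = sim_config or default_config()
    rng_tr = np.random.default_rng(seed * 2 + 1)
    rng_te = np.random.default_rng(seed * 2 + 2)
    frames_tr = [simulate_frame(l, cfg, rng_tr) for l in labels]
    frames_te = [simulate_frame(l, cfg, rng_te) for l in labels]
    ds_tr = build_dataset(frames_tr, region, noise_ratio_train, n_rows_train, seed=seed * 7 + 3, label_vector=tuple(labels))
    ds_te = build_dataset(frames_te, region, noise_ratio_test, n_rows_test, seed=seed * 7 + 4, label_vector=tuple(labels))
    return ds_tr, ds_te


def split_dataset(dataset: LabeledDataset, test_size: float = 0.2, seed: int = 0):
    """Stratified 80/20 hold-out split of one dataset."""
    idx_tr, idx_te = train_test_split(
        np.arange(len(dataset)),
        test_size=test_size,
        stratify=dataset.y,
        random_state=seed % (2**31),
    )
    def sub(idx):
        return LabeledDataset(
            X=dataset.X[idx], y=dataset.y[idx], region=dataset.region,
            label_vector=dataset.label_vector, noise_ratio=dataset.noise_ratio,
            seed=dataset.seed,
        )
    return sub(idx_tr), sub(idx_te)


@dataclass
class AblationReport:
    """Test accuracy over the regions x noise-ratios grid for one optimizer."""

    grid: pd.DataFrame  # columns: region, noise_ratio, accuracy, tol_accuracy
    optimizer: str
    failures: list = field(default_factory=list)

    def cell(self, region: str, noise_ratio: float) -> float:
        sel = (self.grid["region"] == region) & np.isclose(self.grid["noise_ratio"], noise_ratio)
        return float(self.grid.loc[sel, "accuracy"].iloc[0])


def run_ablation(
    regions: Sequence[RegionSpec | str],
    noise_ratios: Sequence[float] = NOISE_RATIOS,
    optimizer: Literal["fixed", "grid", "bayes"] = "fixed",
    base_seed: int = 0,
    epochs: int = 30,
    n_rows_train: int = 200,
    n_rows_test: int = 50,
    sim_config: SimulatorConfig | None = None,
    search_budget: int = 5,
) -> AblationReport:
    """Train and score one model per (region, noise ratio) cell.

    ``optimizer='fixed'`` trains the best-found reported configuration;
    ``'grid'`` / ``'bayes'`` first run a small budgeted search over the
    learning rate before the final fit.  Per-cell seeds derive
    deterministically from ``base_seed`` and the cell index; cell failures
    are recorded and the grid continues.
    """
    from . import hyperopt as hp

    regions = [REGIONS[r] if isinstance(r, str) else r for r in regions]
    records, failures = [], []
    for i, region in enumerate(regions):
        for j, ratio in enumerate(noise_ratios):
            cell_seed = (base_seed * 1_000 + i * 100 + j) % (2**30)
            try:
                ds_tr, ds_te = train_test_datasets(
                    region, ratio, ratio, cell_seed, n_rows_train, n_rows_test, sim_config
                )
                n_blocks = 2 if len(region) >= 4 else 1
                base = model_mod.best_reported_config(epochs=epochs, seed=cell_seed, n_blocks=n_blocks)
                if optimizer == "fixed":
                    tm = model_mod.train(
                        model_mod.build_model(base, len(region), len(ds_tr.label_vector)), ds_tr, base
                    )
                elif optimizer == "grid":
                    lr_grid = [3e-4, 9e-4, 3e-3][: max(search_budget, 2)]
                    space = hp.SearchSpace(values={"learning_rate": lr_grid})
                    res = hp.grid_search(space, ds_tr, k_folds=2, seed=cell_seed, base_config=base)
                    tm = res.refit_model
                else:
                    space = hp.SearchSpace(bounds={"learning_rate": (1e-4, 1e-2, "log-real")})
                    res = hp.bayes_opt(
                        space, ds_tr, n_trials=max(search_budget, 5), seed=cell_seed,
                        k_folds=2, base_config=base,
                    )
                    tm = res.refit_model
                records.append(
                    {
                        "region": region.name,
                        "noise_ratio": ratio,
                        "accuracy": accuracy(tm, ds_te),
                        "tol_accuracy": tolerance_accuracy(tm, ds_te),
                        "seed": cell_seed,
                    }
                )
            except Exception as e:  # noqa: BLE001 - grid must continue
                failures.append({"region": region.name, "noise_ratio": ratio, "error": str(e)})
    return AblationReport(grid=pd.DataFrame(records), optimizer=optimizer, failures=failures)
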