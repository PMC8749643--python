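"""Normalization, spectral-region selection, and noise-augmented dataset assembly.

Each measured curve is min-max normalized to [0, 1] over its own channels:

    I_norm = (I_eff - I_min) / (I_max - I_min)

The training set is built from one representative curve per SpO2 level
(81, 83, ..., 99 %), each expanded to a fixed number of rows by injecting
independent multiplicative uniform noise — the augmentation that gives the
classifier its tolerance to sensor fluctuations.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .simulator import STANDARD_CENTERS_NM, SpectralFrame

__all__ = [
    "RegionSpec",
    "REGIONS",
    "LabeledDataset",
    "DEFAULT_LABELS",
    "NOISE_RATIOS",
    "normalize",
    "select_region",
    "augment",
    "build_dataset",
]

#: The ten SpO2 class labels, percent, ascending in steps of two.
DEFAULT_LABELS = (81, 83, 85, 87, 89, 91, 93, 95, 97, 99)

#: The studied augmentation noise ratios.
NOISE_RATIOS = (0.0, 0.01, 0.02, 0.05, 0.10)


@dataclass(frozen=True)
class RegionSpec:
    """A named subset of the 12 channel centers, ascending."""

    name: str
    centers_nm: tuple[int, ...]

    def __post_init__(self):
        if not self.centers_nm:
            raise ValueError("region must contain at least one channel")
        if any(b <= a for a, b in zip(self.centers_nm, self.centers_nm[1:])):
            raise ValueError("region centers must be strictly ascending")
        unknown = set(self.centers_nm) - set(STANDARD_CENTERS_NM)
        if unknown:
            raise ValueError(f"unknown channel centers: {sorted(unknown)}")

    def __len__(self) -> int:
        return len(self.centers_nm)

    @property
    def columns(self) -> list[str]:
        return [f"nm{c}" for c in self.centers_nm]


REGIONS: dict[str, RegionSpec] = {
    name: RegionSpec(name, centers)
    for name, centers in {
        "FIRST": (450, 500, 550, 570, 600, 610),
        "SECOND": (650, 680, 730, 760, 810, 860),
        "FULL": STANDARD_CENTERS_NM,
        "S11": (450, 500, 550),
        "S12": (500, 550, 570),
        "S13": (570, 600, 610),
        "S14": (450, 570, 610),
        "S21": (650, 680, 730),
        "S22": (730, 760, 810),
        "S23": (760, 810, 860),
        "S24": (650, 760, 860),
    }.items()
}


@dataclass
class LabeledDataset:
    """Normalized spectra rows with SpO2 labels for one region/noise condition."""

    X: np.ndarray  # rows x channels, values in [0, 1]
    y: np.ndarray  # per-row label, percent
    region: RegionSpec
    label_vector: tuple[int, ...] = DEFAULT_LABELS
    noise_ratio: float = 0.0
    seed: int = 0

    def __post_init__(self):
        self.X = np.asarray(self.X, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if self.X.ndim != 2 or self.X.shape[0] != len(self.y):
            raise ValueError("X must be 2-D with one label per row")
        if self.X.shape[1] != len(self.region):
            raise ValueError("column count must match region width")
        if np.any(self.X < 0) or np.any(self.X > 1):
            raise ValueError("normalized intensities must lie in [0, 1]")
        extra = set(np.unique(self.y)) - set(float(v) for v in self.label_vector)
        if extra:
            raise ValueError(f"labels outside label_vector: {sorted(extra)}")

    def __len__(self) -> int:
        return self.X.shape[0]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.X, columns=self.region.columns)
        df.insert(0, "label", self.y.astype(int))
        return df


def normalize(raw_values: np.ndarray) -> np.ndarray:
    """Min-max normalize one curve (or each row of a matrix) to [0, 1].

    A constant curve has no shape to preserve; it maps to all-zeros with a
    warning rather than failing, so batch runs survive pathological frames.
    """
    x = np.asarray(raw_values, dtype=float)
    one_d = x.ndim == 1
    x = np.atleast_2d(x)
    if x.shape[1] < 2:
        raise ValueError("need at least 2 channels to normalize")
    lo = x.min(axis=1, keepdims=True)
    hi = x.max(axis=1, keepdims=True)
    rng = hi - lo
    degenerate = rng[:, 0] == 0
    if degenerate.any():
        warnings.warn(
            f"{int(degenerate.sum())} constant curve(s) normalized to zeros",
            stacklevel=2,
        )
    safe = np.where(rng == 0, 1.0, rng)
    out = (x - lo) / safe
    out[degenerate] = 0.0
    return out[0] if one_d else out


def select_region(data, region: RegionSpec):
    """Restrict a frame list, DataFrame or LabeledDataset to a region's channels."""
    if isinstance(data, LabeledDataset):
        idx = _column_indices(data.region.centers_nm, region)
        return LabeledDataset(
            X=data.X[:, idx],
            y=data.y,
            region=region,
            label_vector=data.label_vector,
            noise_ratio=data.noise_ratio,
            seed=data.seed,
        )
    if isinstance(data, pd.DataFrame):
        missing = [c for c in region.columns if c not in data.columns]
        if missing:
            raise KeyError(f"input lacks channel column(s) {missing} for region {region.name}")
        keep = [c for c in data.columns if not c.startswith("nm")] + region.columns
        return data[keep]
    # sequence of SpectralFrames -> matrix of DC intensities at region channels
    frames = list(data)
    mat = np.empty((len(frames), len(region)))
    for i, fr in enumerate(frames):
        idx = _column_indices(tuple(int(c) for c in fr.centers_nm), region)
        mat[i] = fr.dc[idx]
    return mat


def _column_indices(available: tuple[int, ...], region: RegionSpec) -> list[int]:
    missing = [c for c in region.centers_nm if c not in available]
    if missing:
        raise KeyError(f"missing channel(s) {missing} for region {region.name}")
    return [available.index(c) for c in region.centers_nm]


def augment(
    spectrum: np.ndarray,
    noise_ratio: float,
    n_rows: int = 1000,
    seed: int = 0,
) -> np.ndarray:
    """Expand one normalized curve to ``n_rows`` noisy replicas.

    Each entry is perturbed multiplicatively by an independent draw from
    Uniform(-noise_ratio, +noise_ratio) and clipped back to [0, 1].
    """
    if not 0.0 <= noise_ratio <= 0.10:
        raise ValueError("noise_ratio must be in [0, 0.10]")
    if n_rows < 1:
        raise ValueError("n_rows must be positive")
    v = np.asarray(spectrum, dtype=float)
    if v.ndim != 1:
        raise ValueError("augment expects a single curve")
    rng = np.random.default_rng(seed)
    u = rng.uniform(-noise_ratio, noise_ratio, size=(n_rows, v.size))
    return np.clip(v[None, :] * (1.0 + u), 0.0, 1.0)


def build_dataset(
    frames: list[SpectralFrame],
    region: RegionSpec,
    noise_ratio: float = 0.02,
    n_rows_per_label: int = 1000,
    seed: int = 0,
    label_vector: tuple[int, ...] = DEFAULT_LABELS,
) -> LabeledDataset:
    """Assemble the classifier's training table from one clean frame per label.

    Each frame's DC curve is restricted to ``region``, normalized, expanded to
    ``n_rows_per_label`` noisy rows, and the pooled rows are shuffled under
    ``seed``.
    """
    by_label: dict[float, SpectralFrame] = {}
    for fr in frames:
        if fr.spo2_label is None:
            raise ValueError("all frames must be labeled")
        if fr.spo2_label in by_label:
            raise ValueError(f"duplicate frame for label {fr.spo2_label}")
        by_label[fr.spo2_label] = fr
    missing = [l for l in label_vector if float(l) not in by_label]
    if missing:
        raise ValueError(f"missing frames for label(s) {missing}")

    rng = np.random.default_rng(seed)
    blocks, labels = [], []
    for i, lab in enumerate(label_vector):
        fr = by_label[float(lab)]
        curve = select_region([fr], region)[0]
        normed = normalize(curve)
        # per-label child seed keeps augmentation independent across labels
        blocks.append(augment(normed, noise_ratio, n_rows_per_label, seed=seed * 1009 + i))
        labels.append(np.full(n_rows_per_label, float(lab)))
    X = np.vstack(blocks)
    y = np.concatenate(labels)
    order = rng.permutation(len(y))
    return LabeledDataset(
        X=X[order],
        y=y[order],
        region=region,
        label_vector=tuple(label_vector),
        noise_ratio=noise_ratio,
        seed=seed,
    )
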