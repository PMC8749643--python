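"""Physics-grounded generator of labeled finger-transmission spectra.

Transmission pulse oximetry sends broadband light through the finger and
reads the attenuated intensity on a bank of narrow-band channels.  The
attenuation splits into a quasi-static (DC) part — tissue, venous blood and
the non-pulsatile arterial volume — and a small pulsatile (AC) part caused
by the systolic increase of arterial path length.  Arterial oxygen
saturation s = SpO2/100 sets the mixture of oxy- and deoxyhemoglobin and
therefore the wavelength dependence of both parts via the Beer-Lambert law:

    I(lambda) = I0(lambda) * 10**(-A(lambda)),
    A(lambda) = d * c_Hb * [ s*eps_HbO2(lambda) + (1-s)*eps_Hb(lambda) ]
                + A_tissue(lambda)

with d the effective optical path through blood (cm), c_Hb total hemoglobin
(mmol/L) and eps the molar extinction coefficients (L mmol^-1 cm^-1).
Each sensor channel integrates this over a Gaussian band of the stated FWHM.

The simulator produces frames with the empirical structure of real
multi-channel finger spectra: per-curve-normalized intensities in the
visible "first region" (450-610 nm) are nearly label-independent, while the
red/NIR "second region" (650-860 nm) separates cleanly by saturation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from importlib import resources
from typing import Sequence

import numpy as np

__all__ = [
    "ChromophoreTable",
    "SensorChannel",
    "SimulatorConfig",
    "SpectralFrame",
    "STANDARD_CENTERS_NM",
    "band_weights",
    "absorbance",
    "simulate_frame",
    "generate_sweep",
    "default_channels",
    "default_config",
    "load_chromophore_table",
]

#: The 12 channel centers of the paired 6-channel visible + NIR sensor bank.
STANDARD_CENTERS_NM = (450, 500, 550, 570, 600, 610, 650, 680, 730, 760, 810, 860)

#: Channels read by the wide-band visible sensor (FWHM 40 nm); the remaining
#: six channels belong to the narrow-band NIR sensor (FWHM 20 nm).
_WIDE_BAND_CENTERS = frozenset({450, 500, 550, 570, 600, 650})


@dataclass(frozen=True)
class ChromophoreTable:
    """Molar extinction of deoxy- (Hb) and oxyhemoglobin (HbO2) by wavelength.

    Units: wavelengths in nm, extinctions in L mmol^-1 cm^-1.
    """

    wavelength_nm: np.ndarray
    eps_hb: np.ndarray
    eps_hbo2: np.ndarray

    def __post_init__(self):
        wl = np.asarray(self.wavelength_nm, dtype=float)
        hb = np.asarray(self.eps_hb, dtype=float)
        ox = np.asarray(self.eps_hbo2, dtype=float)
        object.__setattr__(self, "wavelength_nm", wl)
        object.__setattr__(self, "eps_hb", hb)
        object.__setattr__(self, "eps_hbo2", ox)
        if wl.ndim != 1 or len(wl) < 2:
            raise ValueError("chromophore table needs at least two wavelengths")
        if not np.all(np.diff(wl) > 0):
            raise ValueError("wavelengths must be strictly ascending")
        if wl.min() < 400 or wl.max() > 1100:
            raise ValueError("wavelengths must lie in [400, 1100] nm")
        if len(hb) != len(wl) or len(ox) != len(wl):
            raise ValueError("extinction columns must match wavelength column")
        if np.any(hb <= 0) or np.any(ox <= 0):
            raise ValueError("extinction values must be positive")
        # Red-region contrast: deoxyhemoglobin dominates near 660 nm.
        near_red = (wl >= 630) & (wl <= 690)
        if near_red.any() and not np.all(hb[near_red] > ox[near_red]):
            raise ValueError("expected eps_Hb > eps_HbO2 near 660 nm")

    def eps_at(self, wavelengths_nm: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Linear interpolation of both extinction spectra (edge-clamped)."""
        wl = np.asarray(wavelengths_nm, dtype=float)
        return (
            np.interp(wl, self.wavelength_nm, self.eps_hb),
            np.interp(wl, self.wavelength_nm, self.eps_hbo2),
        )


def load_chromophore_table() -> ChromophoreTable:
    """Load the packaged Hb/HbO2 extinction fixture (standard compilation values)."""
    ref = resources.files("oxispec").joinpath("data/chromophores.csv")
    raw = np.genfromtxt(str(ref), delimiter=",", names=True)
    return ChromophoreTable(
        wavelength_nm=raw["wavelength_nm"],
        eps_hb=raw["eps_hb"],
        eps_hbo2=raw["eps_hbo2"],
    )


@dataclass(frozen=True)
class SensorChannel:
    """One spectral channel: Gaussian band at ``center_nm`` with the given FWHM."""

    center_nm: float
    fwhm_nm: float
    adc_bits: int = 16

    def __post_init__(self):
        if self.fwhm_nm <= 0:
            raise ValueError("fwhm_nm must be positive")
        if self.adc_bits < 1:
            raise ValueError("adc_bits must be >= 1")

    @property
    def adc_max(self) -> int:
        return 2**self.adc_bits - 1


def default_channels(centers_nm: Sequence[float] = STANDARD_CENTERS_NM) -> list[SensorChannel]:
    """Channels with the sensor bank's FWHM assignment (40 nm visible, 20 nm NIR)."""
    out = []
    for c in centers_nm:
        if c not in STANDARD_CENTERS_NM:
            raise ValueError(f"unknown channel center {c} nm")
        fwhm = 40.0 if c in _WIDE_BAND_CENTERS else 20.0
        out.append(SensorChannel(center_nm=float(c), fwhm_nm=fwhm, adc_bits=16))
    return out


@dataclass(frozen=True)
class SimulatorConfig:
    """Physical parameters of the synthetic finger.

    path_length_cm is the effective optical path through blood, i.e. the
    geometric finger thickness times the blood volume fraction; a few
    hundredths of a cm is typical for transilluminated finger pulp.
    tissue_od and source_intensity are per-channel arrays aligned with
    ``channels``.
    """

    chromophores: ChromophoreTable
    channels: tuple[SensorChannel, ...]
    path_length_cm: float = 0.2
    hb_total: float = 2.3  # mmol/L, ~150 g/L hemoglobin
    pulsatile_fraction: float = 0.02
    tissue_od: np.ndarray = None
    source_intensity: np.ndarray = None
    read_noise_counts: float = 80.0
    seed: int = 0

    def __post_init__(self):
        if self.path_length_cm <= 0:
            raise ValueError("path_length_cm must be positive")
        if not 0 <= self.pulsatile_fraction < 0.2:
            raise ValueError("pulsatile_fraction must be in [0, 0.2)")
        n = len(self.channels)
        tod = np.zeros(n) if self.tissue_od is None else np.asarray(self.tissue_od, float)
        src = (
            np.full(n, 60000.0)
            if self.source_intensity is None
            else np.broadcast_to(np.asarray(self.source_intensity, float), (n,)).copy()
        )
        if len(tod) != n:
            raise ValueError("tissue_od must have one entry per channel")
        if np.any(src <= 0):
            raise ValueError("source_intensity must be positive per channel")
        object.__setattr__(self, "tissue_od", tod)
        object.__setattr__(self, "source_intensity", src)

    def with_(self, **kwargs) -> "SimulatorConfig":
        return replace(self, **kwargs)


def _tissue_od_profile(centers_nm: np.ndarray, od_450: float = 3.0, decay_nm: float = 100.0) -> np.ndarray:
    # Single-exponential bloodless-tissue baseline: strong attenuation in the
    # blue/green falling off toward the NIR window.
    return od_450 * np.exp(-(np.asarray(centers_nm, float) - 450.0) / decay_nm)


def default_config(
    centers_nm: Sequence[float] = STANDARD_CENTERS_NM,
    seed: int = 0,
    **overrides,
) -> SimulatorConfig:
    """Default simulator: 12-channel bank, realistic finger-scale parameters."""
    channels = tuple(default_channels(centers_nm))
    centers = np.array([ch.center_nm for ch in channels])
    cfg = SimulatorConfig(
        chromophores=load_chromophore_table(),
        channels=channels,
        tissue_od=_tissue_od_profile(centers),
        seed=seed,
    )
    return cfg.with_(**overrides) if overrides else cfg


@dataclass
class SpectralFrame:
    """One synthetic reading: per-channel DC level and AC pulsation amplitude."""

    channels: tuple[SensorChannel, ...]
    dc: np.ndarray  # ADC counts
    ac: np.ndarray  # ADC counts
    spo2_label: float | None = None
    timestamp: float = 0.0
    underflow: np.ndarray = None  # per-channel flag: quantized to 0
    saturated: np.ndarray = None  # per-channel flag: clipped at ADC max

    def __post_init__(self):
        self.dc = np.asarray(self.dc, dtype=np.int64)
        self.ac = np.asarray(self.ac, dtype=np.int64)
        n = len(self.channels)
        if self.underflow is None:
            self.underflow = np.zeros(n, dtype=bool)
        if self.saturated is None:
            self.saturated = np.zeros(n, dtype=bool)
        if np.any(self.ac < 0) or np.any(self.dc < self.ac):
            raise ValueError("frame requires dc >= ac >= 0 per channel")
        for ch, d in zip(self.channels, self.dc):
            if not 0 <= d <= ch.adc_max:
                raise ValueError("dc outside ADC range")

    @property
    def centers_nm(self) -> np.ndarray:
        return np.array([ch.center_nm for ch in self.channels])


def band_weights(channel: SensorChannel, grid_step_nm: float = 1.0) -> tuple[np.ndarray, np.ndarray]:
    """Gaussian band profile of a channel on a wavelength grid.

    Returns ``(grid_nm, weights)`` with the Gaussian (sigma = FWHM/2.355)
    truncated at +/- 2*FWHM and weights normalized to sum to 1.
    """
    if grid_step_nm <= 0:
        raise ValueError("grid_step_nm must be positive")
    half = 2.0 * channel.fwhm_nm
    grid = np.arange(channel.center_nm - half, channel.center_nm + half + grid_step_nm / 2, grid_step_nm)
    sigma = channel.fwhm_nm / 2.355
    w = np.exp(-0.5 * ((grid - channel.center_nm) / sigma) ** 2)
    return grid, w / w.sum()


def absorbance(spo2_fraction: float, channel: SensorChannel, cfg: SimulatorConfig, *, path_scale: float = 1.0) -> float:
    """Band-averaged optical density of the blood-plus-tissue path at one channel.

    ``spo2_fraction`` is s in [0, 1]; ``path_scale`` scales the blood path only
    (used internally for the systolic path increase).
    """
    s = float(spo2_fraction)
    if not 0.0 <= s <= 1.0:
        raise ValueError("spo2_fraction must be in [0, 1]")
    grid, w = band_weights(channel)
    eps_hb, eps_hbo2 = cfg.chromophores.eps_at(grid)
    eps_mix = s * eps_hbo2 + (1.0 - s) * eps_hb
    blood = cfg.path_length_cm * path_scale * cfg.hb_total * float(w @ eps_mix)
    try:
        idx = next(i for i, ch in enumerate(cfg.channels) if ch.center_nm == channel.center_nm)
        tissue = float(cfg.tissue_od[idx])
    except StopIteration:
        tissue = 0.0
    return blood + tissue


def _transmitted(spo2_fraction: float, cfg: SimulatorConfig, path_scale: float) -> np.ndarray:
    a = np.array([absorbance(spo2_fraction, ch, cfg, path_scale=path_scale) for ch in cfg.channels])
    return cfg.source_intensity * 10.0 ** (-a)


def simulate_frame(
    spo2_percent: float,
    cfg: SimulatorConfig,
    rng: np.random.Generator,
    timestamp: float = 0.0,
) -> SpectralFrame:
    """Simulate one labeled reading.

    DC is the diastolic transmitted intensity (plus sensor read noise); AC is
    the drop caused by the systolic increase of the arterial blood path by
    ``pulsatile_fraction`` of the baseline blood path.  Both are quantized
    round-half-even to ADC integers; underflow/saturation is flagged.
    """
    if not 81.0 <= spo2_percent <= 99.0:
        raise ValueError("spo2_percent must be in [81, 99]")
    s = spo2_percent / 100.0
    dc_diastole = _transmitted(s, cfg, path_scale=1.0)
    dc_systole = _transmitted(s, cfg, path_scale=1.0 + cfg.pulsatile_fraction)
    ac_exact = dc_diastole - dc_systole
    dc_noisy = dc_diastole + rng.normal(0.0, cfg.read_noise_counts, size=len(cfg.channels))

    adc_max = np.array([ch.adc_max for ch in cfg.channels])
    dc_q = np.clip(np.round(dc_noisy), 0, adc_max).astype(np.int64)
    ac_q = np.clip(np.round(ac_exact), 0, adc_max).astype(np.int64)
    ac_q = np.minimum(ac_q, dc_q)
    return SpectralFrame(
        channels=cfg.channels,
        dc=dc_q,
        ac=ac_q,
        spo2_label=float(spo2_percent),
        timestamp=timestamp,
        underflow=(dc_q == 0),
        saturated=(dc_q == adc_max),
    )


def generate_sweep(
    labels: Sequence[float],
    n_per_label: int,
    cfg: SimulatorConfig,
    rng: np.random.Generator,
    dt_s: float = 0.7,
) -> list[SpectralFrame]:
    """``n_per_label`` frames per label, time-stamped at the sensor cadence."""
    labels = list(labels)
    if not labels:
        raise ValueError("label vector must be non-empty")
    if n_per_label < 1:
        raise ValueError("n_per_label must be positive")
    if any(b <= a for a, b in zip(labels, labels[1:])):
        warnings.warn("label vector is not strictly ascending", stacklevel=2)
    frames = []
    t = 0.0
    for lab in labels:
        for _ in range(n_per_label):
            frames.append(simulate_frame(lab, cfg, rng, timestamp=t))
            t += dt_s
    return frames
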