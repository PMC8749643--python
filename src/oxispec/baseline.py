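"""Classical dual-wavelength ratio-of-ratios SpO2 estimation.

The traditional pulse oximeter compares the pulsatile attenuation at a red
and a near-infrared wavelength.  With DC the quasi-static transmitted
intensity and AC the pulsatile drop, the exact absorption ratio is

    Q = ln((DC1 - AC1)/DC1) / ln((DC2 - AC2)/DC2)
      = ln(1 - AC1/DC1) / ln(1 - AC2/DC2)

and, in the small-signal regime AC/DC << 1, the familiar first-order form

    Q ~= (AC1/DC1) / (AC2/DC2).

Q falls as saturation rises (deoxyhemoglobin dominates red absorption), and
an empirical linear calibration SpO2 = intercept - slope * Q maps it to a
percentage.  This module is the comparator and sanity oracle for the
multi-wavelength classifier.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np

from .simulator import SpectralFrame

__all__ = [
    "PpgPair",
    "QValue",
    "q_exact",
    "q_approx",
    "LinearCalibration",
    "fit_calibration",
    "spo2_from_q",
    "q_from_frame",
    "DEFAULT_PAIRING_NM",
]

#: Default red / NIR channel pairing within the sensor bank's range
#: (mirrors the classical 660/940 nm pairing).
DEFAULT_PAIRING_NM = (650, 860)


@dataclass(frozen=True)
class PpgPair:
    """AC/DC intensities (counts) at the two wavelengths of a reading."""

    ac1: float
    dc1: float
    ac2: float
    dc2: float

    def __post_init__(self):
        if self.dc1 <= 0 or self.dc2 <= 0:
            raise ValueError("DC intensities must be positive")
        if not (0 <= self.ac1 < self.dc1 and 0 <= self.ac2 < self.dc2):
            raise ValueError("requires 0 <= AC < DC on both channels")


@dataclass(frozen=True)
class QValue:
    q: float
    method: Literal["exact", "approximate"]

    def __post_init__(self):
        if not np.isfinite(self.q):
            raise ValueError("Q must be finite")


def q_exact(p: PpgPair) -> QValue:
    """Exact log-ratio Q; undefined when the reference channel has no pulsation."""
    if p.ac2 == 0:
        raise ZeroDivisionError("AC2 = 0 makes the exact Q ratio undefined")
    q = np.log1p(-p.ac1 / p.dc1) / np.log1p(-p.ac2 / p.dc2)
    return QValue(q=float(q), method="exact")


def q_approx(p: PpgPair) -> QValue:
    """First-order (ratio-of-ratios) Q, valid for AC/DC << 1."""
    if p.ac2 == 0:
        raise ZeroDivisionError("AC2 = 0 makes the ratio of ratios undefined")
    q = (p.ac1 / p.dc1) / (p.ac2 / p.dc2)
    return QValue(q=float(q), method="approximate")


@dataclass(frozen=True)
class LinearCalibration:
    """Empirical map SpO2 = intercept - slope * Q, clamped to [0, 100]."""

    slope: float
    intercept: float


def spo2_from_q(q: QValue | float, calibration: LinearCalibration) -> float:
    qv = q.q if isinstance(q, QValue) else float(q)
    est = calibration.intercept - calibration.slope * qv
    return float(np.clip(est, 0.0, 100.0))


def q_from_frame(
    frame: SpectralFrame,
    pairing_nm: tuple[float, float] = DEFAULT_PAIRING_NM,
    method: Literal["exact", "approximate"] = "exact",
) -> QValue:
    """Extract the dual-wavelength Q from one frame's AC/DC decomposition."""
    centers = list(frame.centers_nm)
    try:
        i1, i2 = centers.index(pairing_nm[0]), centers.index(pairing_nm[1])
    except ValueError as e:
        raise KeyError(f"frame lacks pairing channels {pairing_nm}") from e
    pair = PpgPair(
        ac1=float(frame.ac[i1]),
        dc1=float(frame.dc[i1]),
        ac2=float(frame.ac[i2]),
        dc2=float(frame.dc[i2]),
    )
    return q_exact(pair) if method == "exact" else q_approx(pair)


def fit_calibration(
    frames: Sequence[SpectralFrame],
    pairing_nm: tuple[float, float] = DEFAULT_PAIRING_NM,
    method: Literal["exact", "approximate"] = "exact",
) -> LinearCalibration:
    """Least-squares fit of the linear Q -> SpO2 map on labeled frames."""
    qs, labels = [], []
    for fr in frames:
        if fr.spo2_label is None:
            raise ValueError("calibration frames must be labeled")
        qs.append(q_from_frame(fr, pairing_nm, method).q)
        labels.append(fr.spo2_label)
    qs, labels = np.asarray(qs), np.asarray(labels)
    if len(qs) < 2 or np.ptp(qs) == 0:
        raise ValueError("need at least two distinct Q values to calibrate")
    # SpO2 = intercept - slope*q  <=>  regression of labels on -q
    coef = np.polyfit(qs, labels, 1)
    return LinearCalibration(slope=float(-coef[0]), intercept=float(coef[1]))


def predict_frames(
    frames: Sequence[SpectralFrame],
    calibration: LinearCalibration,
    pairing_nm: tuple[float, float] = DEFAULT_PAIRING_NM,
    method: Literal["exact", "approximate"] = "exact",
) -> np.ndarray:
    """Per-frame SpO2 estimates from the calibrated dual-wavelength ratio."""
    return np.array(
        [spo2_from_q(q_from_frame(fr, pairing_nm, method), calibration) for fr in frames]
    )
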