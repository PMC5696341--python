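"""Single-wavelength calcium calibration for OGB-1.

Fluorescence of a non-ratiometric indicator maps to free calcium through

    Ca(t) = Kd * (F(t) - Fmin) / (Fmax - F(t))

where ``Kd`` = 170 nM for Oregon Green BAPTA-1, ``Fmax`` is the per-cell
fluorescence at indicator saturation (ionomycin) and ``Fmin`` at zero
calcium (EDTA).  Both levels are estimated per cell from the terminal
acquisition phases.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .segmentation import CellTrace

__all__ = [
    "OGB1_KD_NM",
    "CalibrationConstants",
    "CalciumTrace",
    "estimate_fmax",
    "estimate_fmin",
    "estimate_constants",
    "calibrate",
]

#: Dissociation constant of the OGB-1/calcium complex, nM.
OGB1_KD_NM = 170.0

#: Number of terminal samples whose median defines a plateau level.
PLATEAU_SAMPLES = 30


@dataclass
class CalibrationConstants:
    """Per-cell calibration levels and the indicator dissociation constant."""

    fmin: float
    fmax: float
    kd: float = OGB1_KD_NM
    fmin_n: int = 0
    fmax_n: int = 0

    def __post_init__(self) -> None:
        if not self.kd > 0:
            raise ValueError("kd must be positive")
        if not self.fmax > self.fmin:
            raise ValueError("fmax must exceed fmin")


@dataclass
class CalciumTrace:
    """Calibrated calcium concentration (nM) over the flow phase."""

    cell_id: int
    t: np.ndarray
    ca: np.ndarray
    clipped: np.ndarray

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.ca = np.asarray(self.ca, dtype=float)
        self.clipped = np.asarray(self.clipped, dtype=bool)
        if not (len(self.t) == len(self.ca) == len(self.clipped)):
            raise ValueError("t, ca and clipped must have equal lengths")

    @property
    def dt(self) -> float:
        return float(self.t[1] - self.t[0]) if len(self.t) > 1 else 1.0


def _plateau_level(trace: CellTrace, phase: str, k: int) -> tuple[float, int]:
    f = trace.f[trace.phase_mask(phase)]
    if f.size < k:
        raise ValueError(
            f"phase {phase!r} has {f.size} samples; at least {k} are required"
        )
    return float(np.median(f[-k:])), int(min(k, f.size))


def estimate_fmax(trace: CellTrace, k: int = PLATEAU_SAMPLES) -> float:
    """Saturated-indicator level: median of the last ``k`` ionomycin samples."""
    level, _ = _plateau_level(trace, "ionomycin", k)
    return level


def estimate_fmin(trace: CellTrace, k: int = PLATEAU_SAMPLES) -> float:
    """Zero-calcium level: median of the last ``k`` EDTA samples."""
    level, _ = _plateau_level(trace, "edta", k)
    return level


def estimate_constants(trace: CellTrace, kd: float = OGB1_KD_NM) -> CalibrationConstants:
    fmax, n_max = _plateau_level(trace, "ionomycin", PLATEAU_SAMPLES)
    fmin, n_min = _plateau_level(trace, "edta", PLATEAU_SAMPLES)
    return CalibrationConstants(fmin=fmin, fmax=fmax, kd=kd, fmin_n=n_min, fmax_n=n_max)


def calibrate(trace: CellTrace, constants: CalibrationConstants) -> CalciumTrace:
    """Apply the calibration formula to the flow-phase samples of ``trace``.

    Samples at or beyond the calibration range (F <= Fmin, or F within a
    numerical guard of Fmax) cannot be converted meaningfully: they are
    clamped into [0, 10*Kd] and flagged ``clipped`` instead of propagating
    negative concentrations or infinities.
    """
    fmin, fmax, kd = constants.fmin, constants.fmax, constants.kd
    eps = 1e-6 * (fmax - fmin)
    mask = trace.phase_mask("flow")
    t = trace.t[mask]
    f = trace.f[mask]

    low = f <= fmin
    high = f >= fmax - eps
    ca = np.empty_like(f)
    ok = ~(low | high)
    ca[ok] = kd * (f[ok] - fmin) / (fmax - f[ok])
    ca[low] = 0.0
    ca[high] = 10.0 * kd
    # F == fmin maps to exactly 0 by the formula; keep that identity
    ca[f == fmin] = 0.0
    clipped = low | high
    return CalciumTrace(trace.cell_id, t, ca, clipped)
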