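"""Wall-shear maps from gridded velocity fields.

Inputs are already-reconstructed velocity component grids from phase-contrast
velocimetry of a parallel-plate flow chamber.  Post-processing follows the
acquisition's bias corrections — subtraction of a no-flow reference and
averaging with a 180-degree-rotated acquisition — and converts speed to wall
shear stress with the parallel-plate result

    tau_w = 6 * mu * Q / (b * h**2),   Q = s_mean * b * h  =>  tau_w = 6 * mu * s_mean / h

where mu is the dynamic viscosity (dyn*s/cm^2), b the voxel width (cm), h the
chamber height (cm) and s_mean the depth-averaged speed (cm/s).  All shear
math is CGS; SI speeds (m/s) are converted on load.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

__all__ = [
    "DEFAULT_VISCOSITY",
    "VelocityField",
    "ShearMap",
    "subtract_baseline",
    "average_rotations",
    "speed_map",
    "shear_from_speed",
    "roi_mean_shear",
]

#: Dynamic viscosity of culture medium at 37 C, dyn*s/cm^2 (overridable).
DEFAULT_VISCOSITY = 0.0078


@dataclass
class VelocityField:
    """Gridded velocity components with chamber geometry."""

    vx: np.ndarray
    vy: np.ndarray
    vz: np.ndarray | None = None
    mask: np.ndarray | None = None  # valid voxels; None = all valid
    b: float = 0.1  # voxel width, cm
    h: float = 0.04  # chamber height, cm
    units: str = "cm/s"  # or "m/s"

    def __post_init__(self) -> None:
        self.vx = np.asarray(self.vx, dtype=float)
        self.vy = np.asarray(self.vy, dtype=float)
        if self.vx.shape != self.vy.shape:
            raise ValueError("vx and vy grids must be congruent")
        if self.vz is not None:
            self.vz = np.asarray(self.vz, dtype=float)
            if self.vz.shape != self.vx.shape:
                raise ValueError("vz grid must be congruent with vx/vy")
        if self.mask is not None:
            self.mask = np.asarray(self.mask, dtype=bool)
            if self.mask.shape != self.vx.shape:
                raise ValueError("mask must be congruent with the velocity grids")
        if not (self.b > 0 and self.h > 0):
            raise ValueError("voxel width b and chamber height h must be positive")
        if self.units not in ("cm/s", "m/s"):
            raise ValueError("units must be 'cm/s' or 'm/s'")

    def components(self) -> list[np.ndarray]:
        comps = [self.vx, self.vy]
        if self.vz is not None:
            comps.append(self.vz)
        return comps


@dataclass
class ShearMap:
    """Wall shear stress per voxel, dyn/cm^2."""

    tau: np.ndarray
    mu: float  # dyn*s/cm^2

    def __post_init__(self) -> None:
        self.tau = np.asarray(self.tau, dtype=float)


def _check_congruent(a: VelocityField, b: VelocityField) -> None:
    if a.vx.shape != b.vx.shape or (a.vz is None) != (b.vz is None):
        raise ValueError("velocity fields are not congruent")


def subtract_baseline(field: VelocityField, no_flow_field: VelocityField) -> VelocityField:
    """Remove gradient-imperfection bias: componentwise difference with a no-flow image."""
    _check_congruent(field, no_flow_field)
    return replace(
        field,
        vx=field.vx - no_flow_field.vx,
        vy=field.vy - no_flow_field.vy,
        vz=None if field.vz is None else field.vz - no_flow_field.vz,
    )


def average_rotations(field_0: VelocityField, field_180: VelocityField) -> VelocityField:
    """Average an acquisition with its 180-degree-about-x re-acquisition.

    The rotated acquisition is re-registered by flipping its row order and
    negating vy (the rotation maps row r -> R-1-r and reverses the y axis;
    vx is preserved), then averaged with the unrotated one.  A directional
    bias that is identical in both acquisitions' vy cancels exactly.
    """
    _check_congruent(field_0, field_180)
    reg_vx = np.flip(field_180.vx, axis=0)
    reg_vy = -np.flip(field_180.vy, axis=0)
    reg_vz = None if field_180.vz is None else np.flip(field_180.vz, axis=0)
    return replace(
        field_0,
        vx=(field_0.vx + reg_vx) / 2.0,
        vy=(field_0.vy + reg_vy) / 2.0,
        vz=None if field_0.vz is None else (field_0.vz + reg_vz) / 2.0,
    )


def speed_map(field: VelocityField) -> np.ndarray:
    """Euclidean speed per voxel in cm/s (SI inputs are converted)."""
    sq = sum(c**2 for c in field.components())
    speed = np.sqrt(sq)
    if field.units == "m/s":
        speed = speed * 100.0
    return speed


def shear_from_speed(
    speed_grid: np.ndarray,
    mu: float = DEFAULT_VISCOSITY,
    b: float = 0.1,
    h: float = 0.04,
    profile: str = "plug",
) -> ShearMap:
    """Wall shear stress from a speed grid (cm/s), dyn/cm^2.

    With ``profile="plug"`` (default) the measured in-plane speed is treated
    as the depth-averaged speed, so Q = s*b*h per voxel and tau = 6*mu*s/h
    (the voxel width cancels).  With ``profile="parabolic"`` the measurement
    is taken as the mid-plane speed of a parabolic profile (1.5x the mean),
    so tau = 4*mu*s/h.
    """
    if not (mu > 0 and b > 0 and h > 0):
        raise ValueError("mu, b and h must be positive")
    speed = np.asarray(speed_grid, dtype=float)
    if profile == "plug":
        tau = 6.0 * mu * speed / h
    elif profile == "parabolic":
        tau = 6.0 * mu * (speed / 1.5) / h
    else:
        raise ValueError("profile must be 'plug' or 'parabolic'")
    return ShearMap(tau=tau, mu=mu)


def roi_mean_shear(shear_map: ShearMap, roi_mask: np.ndarray) -> float:
    """Mean wall shear over a region of interest, dyn/cm^2."""
    roi = np.asarray(roi_mask, dtype=bool)
    if roi.shape != shear_map.tau.shape:
        raise ValueError("ROI mask must be congruent with the shear map")
    if not roi.any():
        raise ValueError("ROI contains no valid voxels")
    return float(shear_map.tau[roi].mean())
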