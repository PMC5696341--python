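"""Cell-shape, junction, polarity and shear-response quantification.

Conventions: the flow axis defaults to +x of the image frame (columns
increase downstream); "downstream" means increasing projection on that axis.
The elongation factor is the cell's pixel-extent along the flow axis divided
by its extent on the perpendicular axis — a projection definition, so a cell
lying perpendicular to flow has EF < 1.  Orientation is the acute angle
(degrees, [0, 90]) between the cell's principal axis (second central
moments) and the flow axis.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit

from .segmentation import CellLabelMap, otsu_threshold

__all__ = [
    "CellShape",
    "PolarizationProfile",
    "ShearResponsePoint",
    "cell_shape_metrics",
    "junction_coverage",
    "intensity_profile",
    "polarization_index",
    "fit_repolarization",
    "classify_golgi_polarity",
    "nuclear_positive_fraction",
    "shear_response_curve",
]

logger = logging.getLogger(__name__)


@dataclass
class CellShape:
    cell_id: int
    elongation_factor: float
    orientation_deg: float  # acute angle to the flow axis, [0, 90]
    length_along_flow: float
    width: float
    centroid: tuple[float, float]  # (x, y)


@dataclass
class PolarizationProfile:
    """Background-subtracted intensity along the cell body, nucleus-normalized.

    ``position`` runs from -1 (upstream cell end) through 0 (nucleus centre)
    to +1 (downstream cell end); each side is rescaled independently.
    """

    cell_id: int
    position: np.ndarray
    intensity: np.ndarray
    time_min: float = float("nan")

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.position.shape != self.intensity.shape:
            raise ValueError("position and intensity must have equal lengths")


@dataclass
class ShearResponsePoint:
    roi_id: int
    shear: float  # dyn/cm^2
    pct_nuclear_positive: float  # %


def _unit(axis) -> np.ndarray:
    u = np.asarray(axis, dtype=float)
    n = np.linalg.norm(u)
    if n == 0:
        raise ValueError("flow axis must be a non-zero vector")
    return u / n


def _touches_border(rows, cols, shape) -> bool:
    return (
        rows.min() == 0 or cols.min() == 0
        or rows.max() == shape[0] - 1 or cols.max() == shape[1] - 1
    )


def cell_shape_metrics(
    labels: CellLabelMap | np.ndarray,
    flow_axis=(1.0, 0.0),
    pixel_size: float = 1.0,
) -> list[CellShape]:
    """Shape descriptors per labelled cell relative to the flow axis.

    Extents are max - min of the pixel-centre projections plus one pixel
    width.  Cells touching the image border are excluded (their extents are
    clipped); the exclusion count is logged.
    """
    lab = labels.labels if isinstance(labels, CellLabelMap) else np.asarray(labels)
    u = _unit(flow_axis)
    v = np.array([-u[1], u[0]])  # perpendicular
    shapes = []
    excluded = 0
    for cid in np.unique(lab[lab > 0]):
        rows, cols = np.nonzero(lab == cid)
        if _touches_border(rows, cols, lab.shape):
            excluded += 1
            continue
        x, y = cols.astype(float), rows.astype(float)
        proj_u = x * u[0] + y * u[1]
        proj_v = x * v[0] + y * v[1]
        length = (proj_u.max() - proj_u.min() + 1.0) * pixel_size
        width = (proj_v.max() - proj_v.min() + 1.0) * pixel_size
        # principal-axis angle from second central moments
        mu20 = np.var(x)
        mu02 = np.var(y)
        mu11 = np.mean((x - x.mean()) * (y - y.mean()))
        theta = 0.5 * math.atan2(2 * mu11, mu20 - mu02)
        phi = math.atan2(u[1], u[0])
        delta = math.degrees(theta - phi)
        orientation = abs(((delta + 90.0) % 180.0) - 90.0)
        shapes.append(CellShape(
            cell_id=int(cid),
            elongation_factor=length / width,
            orientation_deg=orientation,
            length_along_flow=length,
            width=width,
            centroid=(float(x.mean()), float(y.mean())),
        ))
    if excluded:
        logger.info("cell_shape_metrics: excluded %d border-touching cells", excluded)
    return shapes


def junction_coverage(
    junction_image: np.ndarray, labels_or_mask: np.ndarray | CellLabelMap | None = None
) -> tuple[float, float]:
    """(percent covered, percent uncovered) of junction signal over a region.

    The junction image is thresholded by Otsu; coverage is the percentage of
    region pixels above threshold.  The region defaults to the whole image;
    a label map restricts it to labelled pixels; a boolean mask is used as is.
    The two percentages sum to 100 exactly.
    """
    img = np.asarray(junction_image, dtype=float)
    if labels_or_mask is None:
        region = np.ones(img.shape, dtype=bool)
    elif isinstance(labels_or_mask, CellLabelMap):
        region = labels_or_mask.labels > 0
    else:
        arr = np.asarray(labels_or_mask)
        region = arr > 0 if not arr.dtype == bool else arr
    if region.shape != img.shape:
        raise ValueError("junction image and region must be congruent")
    thr = otsu_threshold(img)
    pct_covered = 100.0 * np.count_nonzero(img[region] >= thr) / region.sum()
    return pct_covered, 100.0 - pct_covered


def intensity_profile(
    cell_mask: np.ndarray,
    intensity_image: np.ndarray,
    nucleus_centroid: tuple[float, float],  # (x, y)
    flow_axis=(1.0, 0.0),
    cell_id: int = 0,
    background_percentile: float = 5.0,
) -> PolarizationProfile:
    """Intensity along the cell body parallel to the flow axis.

    Intensity is summed across the perpendicular direction at each integer
    station of the flow-axis projection; the background (5th percentile of
    the raw profile) is subtracted and the result floored at zero.  Each
    side's distance to the nucleus centre is rescaled so the cell ends map
    exactly to -1 and +1.  Border-clipped cells are rejected (their profile
    would be truncated).
    """
    mask = np.asarray(cell_mask).astype(bool)
    img = np.asarray(intensity_image, dtype=float)
    if mask.shape != img.shape:
        raise ValueError("mask and intensity image must be congruent")
    rows, cols = np.nonzero(mask)
    if rows.size == 0:
        raise ValueError("empty cell mask")
    if _touches_border(rows, cols, mask.shape):
        raise ValueError("cell touches the image border; partially visible cells are excluded")
    nx, ny = nucleus_centroid
    if not mask[int(round(ny)), int(round(nx))]:
        raise ValueError("nucleus centroid must lie inside the cell mask")
    u = _unit(flow_axis)
    proj = cols * u[0] + rows * u[1]
    stations = np.round(proj).astype(int)
    s_vals = np.arange(stations.min(), stations.max() + 1)
    profile = np.zeros(s_vals.size)
    np.add.at(profile, stations - stations.min(), img[rows, cols])
    background = np.percentile(profile, background_percentile)
    profile = np.clip(profile - background, 0.0, None)

    s_nuc = nx * u[0] + ny * u[1]
    s_min, s_max = float(s_vals[0]), float(s_vals[-1])
    if not (s_min < s_nuc < s_max):
        raise ValueError("nucleus centroid coincides with a cell end")
    position = np.where(
        s_vals >= s_nuc,
        (s_vals - s_nuc) / (s_max - s_nuc),
        (s_vals - s_nuc) / (s_nuc - s_min),
    )
    return PolarizationProfile(cell_id=cell_id, position=position, intensity=profile)


def polarization_index(profile: PolarizationProfile) -> float:
    """Downstream fraction: area of the profile on position > 0 over total area.

    Trapezoidal areas; the profile is split exactly at position 0 (with linear
    interpolation when no sample falls there).  The mirror identity
    index(mirrored profile) = 1 - index(profile) holds exactly.
    """
    pos = profile.position
    y = profile.intensity
    if np.any(y < 0):
        raise ValueError("profile intensity must be non-negative")
    order = np.argsort(pos, kind="stable")
    pos, y = pos[order], y[order]
    total = np.trapezoid(y, pos)
    if total <= 0:
        raise ValueError("all-zero profile has no polarization index")
    if 0.0 in pos:
        cut = np.searchsorted(pos, 0.0, side="left")
        down = np.trapezoid(y[cut:], pos[cut:])
    else:
        y0 = np.interp(0.0, pos, y)
        cut = np.searchsorted(pos, 0.0)
        down = np.trapezoid(np.concatenate(([y0], y[cut:])), np.concatenate(([0.0], pos[cut:])))
    return float(down / total)


def fit_repolarization(times, indices) -> tuple[float, float, float]:
    """Fit d(t) = d_inf - (d_inf - d0)*exp(-t/tau) to a downstream-fraction series.

    Returns (tau, d0, d_inf) with tau in the units of ``times`` (minutes in
    the standard protocol).  A constant series has no relaxation to fit and
    raises.
    """
    t = np.asarray(times, dtype=float)
    d = np.asarray(indices, dtype=float)
    if t.size != d.size or t.size < 4:
        raise ValueError("need at least 4 matching timepoints")
    if np.ptp(d) < 1e-12:
        raise ValueError("no relaxation: series is constant")

    def model(t, tau, d0, d_inf):
        return d_inf - (d_inf - d0) * np.exp(-t / tau)

    span = max(float(t.max() - t.min()), 1.0)
    p0 = (span / 3.0, float(d[0]), float(d[-1]))
    popt, _ = curve_fit(
        model, t, d, p0=p0,
        bounds=([1e-9, -np.inf, -np.inf], [np.inf, np.inf, np.inf]),
        maxfev=20000, xtol=1e-12, ftol=1e-12,
    )
    tau, d0, d_inf = (float(v) for v in popt)
    return tau, d0, d_inf


def classify_golgi_polarity(
    nucleus_centroid, organelle_centroid, flow_axis=(1.0, 0.0), deadband: float = 1.0
) -> str:
    """'downstream', 'upstream' or 'unpolarized' by the signed nucleus->organelle offset.

    The projection of (organelle - nucleus) on the flow axis decides:
    strictly beyond +deadband is downstream, strictly beyond -deadband is
    upstream, anything inside the closed deadband interval is unpolarized.
    """
    u = _unit(flow_axis)
    d = np.asarray(organelle_centroid, dtype=float) - np.asarray(nucleus_centroid, dtype=float)
    s = float(d[0] * u[0] + d[1] * u[1])
    if s > deadband:
        return "downstream"
    if s < -deadband:
        return "upstream"
    return "unpolarized"


def nuclear_positive_fraction(nuclear_intensities, threshold: float | None = None) -> float:
    """Percentage of cells whose nuclear intensity exceeds the threshold.

    With ``threshold=None`` an Otsu threshold of the pooled intensity
    distribution is used (the choice of threshold is otherwise up to the
    caller, as only the relative response across regions matters).
    """
    vals = np.asarray(nuclear_intensities, dtype=float)
    if vals.size == 0:
        raise ValueError("need at least one cell")
    if threshold is None:
        threshold = otsu_threshold(vals)
    return float(100.0 * np.count_nonzero(vals > threshold) / vals.size)


def shear_response_curve(points) -> dict:
    """Logarithmic fit pct = a*ln(shear) + c of nuclear response vs wall shear.

    ``points`` is a list of :class:`ShearResponsePoint` or an (shear, pct)
    pair of arrays.  Requires >= 3 ROIs with pairwise-distinct positive shear.
    When the two highest-shear points differ by < 2 percentage points their
    mean is reported as ``plateau_level`` (response saturation), else None.
    """
    if isinstance(points, tuple) and len(points) == 2:
        shear = np.asarray(points[0], dtype=float)
        pct = np.asarray(points[1], dtype=float)
    else:
        shear = np.array([p.shear for p in points], dtype=float)
        pct = np.array([p.pct_nuclear_positive for p in points], dtype=float)
    if np.any(shear <= 0):
        raise ValueError("shear values must be positive")
    if np.unique(shear).size < 3 or np.unique(shear).size < shear.size:
        raise ValueError("need at least 3 ROIs with pairwise-distinct shear")
    x = np.log(shear)
    a, c = np.polyfit(x, pct, 1)
    fitted = a * x + c
    ss_res = float(np.sum((pct - fitted) ** 2))
    ss_tot = float(np.sum((pct - pct.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    top = np.argsort(shear)[-2:]
    plateau = float(pct[top].mean()) if abs(pct[top[0]] - pct[top[1]]) < 2.0 else None
    return {"slope": float(a), "intercept": float(c), "r_squared": r2,
            "plateau_level": plateau}
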