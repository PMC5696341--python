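"""Turn a fluorescence movie into per-cell traces.

The processing chain is deliberately minimal: average all frames over time,
apply Otsu's threshold to the average image, label the resulting connected
components, and read out the mean intensity of each labelled cell in every
frame.  Touching cells are *not* split (no watershed); in a confluent
monolayer this under-segments, which is documented as a limitation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

__all__ = [
    "PHASES",
    "FluorescenceMovie",
    "CellLabelMap",
    "CellTrace",
    "temporal_mean",
    "otsu_threshold",
    "label_cells",
    "extract_traces",
]

#: Recognised acquisition phases.  ``flow`` is the recording proper;
#: ``ionomycin`` saturates the indicator (Fmax), ``edta`` chelates free
#: calcium (Fmin); ``none`` marks frames outside the protocol.
PHASES = ("flow", "ionomycin", "edta", "none")

# 4-connectivity structuring element: deterministic labelling across platforms.
_STRUCT4 = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=bool)


@dataclass
class FluorescenceMovie:
    """Multi-frame single-channel recording (time x rows x cols, a.u.)."""

    frames: np.ndarray
    dt: float = 1.0
    phase_per_frame: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 3:
            raise ValueError("frames must be a 3-D array (time, rows, cols)")
        if not self.dt > 0:
            raise ValueError("dt must be positive")
        if self.phase_per_frame is None:
            self.phase_per_frame = np.full(self.frames.shape[0], "flow", dtype=object)
        else:
            self.phase_per_frame = np.asarray(self.phase_per_frame, dtype=object)
            if self.phase_per_frame.shape[0] != self.frames.shape[0]:
                raise ValueError("phase_per_frame length must match frame count")
            bad = set(self.phase_per_frame) - set(PHASES)
            if bad:
                raise ValueError(f"unknown phase labels: {sorted(bad)}")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def t(self) -> np.ndarray:
        return np.arange(self.n_frames) * self.dt


@dataclass
class CellLabelMap:
    """Integer label image; 0 is background, cells are 1..K."""

    labels: np.ndarray
    pixel_size: float | None = None  # um per pixel, optional

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 2:
            raise ValueError("labels must be a 2-D array")
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise ValueError("labels must be integer-valued")

    @property
    def n_cells(self) -> int:
        return int(self.labels.max(initial=0))

    @property
    def cell_ids(self) -> np.ndarray:
        ids = np.unique(self.labels)
        return ids[ids > 0]


@dataclass
class CellTrace:
    """Per-cell fluorescence versus time, with the acquisition phase of each sample."""

    cell_id: int
    t: np.ndarray
    f: np.ndarray
    phase: np.ndarray

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.f = np.asarray(self.f, dtype=float)
        self.phase = np.asarray(self.phase, dtype=object)
        if not (len(self.t) == len(self.f) == len(self.phase)):
            raise ValueError("t, f and phase must have equal lengths")
        if len(self.t) > 1:
            steps = np.diff(self.t)
            if np.any(steps <= 0) or not np.allclose(steps, steps[0]):
                raise ValueError("t must be strictly increasing with a constant step")

    @property
    def dt(self) -> float:
        return float(self.t[1] - self.t[0]) if len(self.t) > 1 else 1.0

    def phase_mask(self, name: str) -> np.ndarray:
        return self.phase == name

    def copy_with(self, f: np.ndarray) -> "CellTrace":
        return CellTrace(self.cell_id, self.t.copy(), np.asarray(f, dtype=float), self.phase.copy())


def temporal_mean(movie: FluorescenceMovie) -> np.ndarray:
    """Pixelwise arithmetic mean over all frames."""
    if movie.n_frames == 0:
        raise ValueError("cannot average an empty movie")
    return movie.frames.mean(axis=0)


def otsu_threshold(image: np.ndarray, n_bins: int = 256) -> float:
    """Otsu's threshold on a histogram of ``n_bins`` bins spanning [min, max].

    The candidate thresholds are the interior bin edges; the returned edge
    maximises the between-class variance of the induced two-class partition
    of the data (class means are computed from the data itself, so the result
    agrees with an exhaustive search over the same candidates).  Ties are
    broken toward the lowest qualifying threshold.  Samples >= the returned
    edge form the foreground class.
    """
    x = np.asarray(image, dtype=float).ravel()
    if x.size == 0 or not np.all(np.isfinite(x)):
        raise ValueError("image must be non-empty and finite")
    lo, hi = float(x.min()), float(x.max())
    if lo == hi:
        raise ValueError("degenerate histogram: image is constant")
    counts, edges = np.histogram(x, bins=n_bins, range=(lo, hi))
    sums, _ = np.histogram(x, bins=n_bins, range=(lo, hi), weights=x)

    n0 = np.cumsum(counts)[:-1].astype(float)
    s0 = np.cumsum(sums)[:-1]
    n1 = x.size - n0
    s1 = x.sum() - s0
    valid = (n0 > 0) & (n1 > 0)
    bcv = np.full(n_bins - 1, -np.inf)
    with np.errstate(invalid="ignore", divide="ignore"):
        diff = s0 / n0 - s1 / n1
    bcv[valid] = (n0 * n1)[valid] * diff[valid] ** 2
    k = int(np.argmax(bcv))  # first maximum -> lowest qualifying edge
    return float(edges[k + 1])


def label_cells(mask: np.ndarray, min_area: int = 0) -> CellLabelMap:
    """Label 4-connected foreground components of ``mask``.

    Components smaller than ``min_area`` pixels are dropped.  Surviving
    components are renumbered 1..K in raster order of their first pixel.
    """
    mask = np.asarray(mask).astype(bool)
    raw, n = ndimage.label(mask, structure=_STRUCT4)
    if n == 0:
        return CellLabelMap(np.zeros_like(raw))
    areas = np.bincount(raw.ravel(), minlength=n + 1)
    keep = np.flatnonzero(areas >= max(min_area, 1))
    keep = keep[keep > 0]
    flat = raw.ravel()
    # raster index of each kept component's first pixel
    first = {lab: np.argmax(flat == lab) for lab in keep}
    order = sorted(keep, key=lambda lab: first[lab])
    out = np.zeros_like(raw)
    for new, lab in enumerate(order, start=1):
        out[raw == lab] = new
    return CellLabelMap(out)


def extract_traces(movie: FluorescenceMovie, labels: CellLabelMap) -> list[CellTrace]:
    """Mean intensity of each labelled cell in every frame."""
    lab = labels.labels
    if lab.shape != movie.frames.shape[1:]:
        raise ValueError("label map shape must match the movie frame shape")
    ids = labels.cell_ids
    if ids.size == 0:
        raise ValueError("label map contains no cells")
    t = movie.t
    flat = movie.frames.reshape(movie.n_frames, -1)
    lab_flat = lab.ravel()
    traces = []
    for cid in ids:
        cols = np.flatnonzero(lab_flat == cid)
        f = flat[:, cols].mean(axis=1)
        traces.append(CellTrace(int(cid), t, f, movie.phase_per_frame))
    return traces
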