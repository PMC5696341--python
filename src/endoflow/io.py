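"""Readers/writers for the pipeline's on-disk formats.

Traces travel as long-format CSV (cell_id, t_s, F_au, phase); movies as
multi-page TIFF; label maps as 16-bit TIFF; velocity/shear grids as CSV with
a JSON sidecar describing shape, units and geometry.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .segmentation import CellLabelMap, CellTrace, FluorescenceMovie

__all__ = [
    "write_traces_csv",
    "read_traces_csv",
    "write_movie_tiff",
    "read_movie_tiff",
    "write_labels_tiff",
    "read_labels_tiff",
    "write_grid_csv",
    "read_grid_csv",
]


def write_traces_csv(traces: list[CellTrace], path) -> None:
    frames = [
        pd.DataFrame({
            "cell_id": tr.cell_id, "t_s": tr.t, "F_au": tr.f, "phase": tr.phase,
        })
        for tr in traces
    ]
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_traces_csv(path) -> list[CellTrace]:
    df = pd.read_csv(path)
    traces = []
    for cid, grp in df.groupby("cell_id", sort=True):
        traces.append(CellTrace(
            int(cid),
            grp["t_s"].to_numpy(float),
            grp["F_au"].to_numpy(float),
            grp["phase"].to_numpy(object),
        ))
    return traces


def write_movie_tiff(movie: FluorescenceMovie, path, sidecar: bool = True) -> None:
    tifffile.imwrite(path, movie.frames.astype(np.float32))
    if sidecar:
        meta = {"dt_s": movie.dt, "phase_per_frame": list(movie.phase_per_frame)}
        Path(str(path) + ".json").write_text(json.dumps(meta))


def read_movie_tiff(path, dt: float | None = None) -> FluorescenceMovie:
    frames = tifffile.imread(path)
    sidecar = Path(str(path) + ".json")
    phases = None
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
        dt = dt if dt is not None else float(meta.get("dt_s", 1.0))
        phases = meta.get("phase_per_frame")
    return FluorescenceMovie(frames, dt=dt or 1.0, phase_per_frame=phases)


def write_labels_tiff(labels: CellLabelMap, path) -> None:
    if labels.n_cells > np.iinfo(np.uint16).max:
        raise ValueError("too many labels for a 16-bit TIFF")
    tifffile.imwrite(path, labels.labels.astype(np.uint16))


def read_labels_tiff(path) -> CellLabelMap:
    return CellLabelMap(tifffile.imread(path).astype(np.int32))


def write_grid_csv(grid: np.ndarray, path, units: str = "", **meta) -> None:
    np.savetxt(path, np.asarray(grid, dtype=float), delimiter=",")
    side = {"shape": list(np.shape(grid)), "units": units, **meta}
    Path(str(path) + ".json").write_text(json.dumps(side))


def read_grid_csv(path) -> tuple[np.ndarray, dict]:
    grid = np.atleast_2d(np.loadtxt(path, delimiter=","))
    sidecar = Path(str(path) + ".json")
    meta = json.loads(sidecar.read_text()) if sidecar.exists() else {}
    return grid, meta
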