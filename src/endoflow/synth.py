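"""Synthetic inputs with recorded ground truth for every pipeline stage.

Everything the analysis consumes can be generated here: calcium traces with
known spikes, bleaching and calibration phases; movies that paint traces into
labelled cells; elliptical monolayers with junction rasters; protein
repolarization time courses; and parallel-plate velocity fields with their
analytic shear truth.  All generators are deterministic given their seed.

The trace generator inverts the calibration formula,

    F(t) = (Fmin*Kd + Fmax*Ca(t)) / (Kd + Ca(t)),

paints the acquisition protocol (flow recording, then ionomycin driving
F -> Fmax, then EDTA driving F -> Fmin), applies a slow bleaching trend, and
adds Gaussian noise.  Spikes are boxcars with durations quantized to the
sampling grid so duration/amplitude ground truth is exact for detector
testing.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from skimage import draw as skdraw
from skimage.segmentation import find_boundaries

from .calibration import OGB1_KD_NM
from .segmentation import CellLabelMap, CellTrace, FluorescenceMovie
from .shear import ShearMap, VelocityField

__all__ = [
    "PhasePlan",
    "TraceGroundTruth",
    "ConditionConfig",
    "SaturationError",
    "SCRAMBLE",
    "KD",
    "condition_preset",
    "synth_trace",
    "true_calcium",
    "synth_condition",
    "synth_movie",
    "MonolayerSample",
    "synth_monolayer",
    "synth_polar_series",
    "synth_velocity_field",
]


class SaturationError(ValueError):
    """A spike would push the fluorescence to the indicator's saturation level."""


@dataclass(frozen=True)
class PhasePlan:
    """Durations (s) of the acquisition phases, in protocol order."""

    flow_s: float = 600.0
    ionomycin_s: float = 180.0
    edta_s: float = 180.0

    def __post_init__(self) -> None:
        if min(self.flow_s, self.ionomycin_s, self.edta_s) <= 0:
            raise ValueError("all phase durations must be positive")


@dataclass
class TraceGroundTruth:
    """Everything needed to synthesise one cell's trace, and to check it later."""

    baseline_ca: float = 120.0  # nM
    spike_onsets: tuple[float, ...] = ()  # s, within the flow phase
    spike_durations: tuple[float, ...] = ()  # s
    spike_amplitudes: tuple[float, ...] = ()  # nM
    # (c0 a.u., c1 a.u./s, c2 a.u./s^2, amp a.u., tau s); trivial trend by default
    bleach_coeffs: tuple[float, float, float, float, float] = (1.0, 0.0, 0.0, 0.0, -200.0)
    noise_sd: float = 0.0  # a.u.
    fmin: float = 100.0  # a.u.
    fmax: float = 600.0  # a.u.
    kd: float = OGB1_KD_NM  # nM
    seed: int = 0
    bleach_mode: str = "multiplicative"  # or "additive"

    def __post_init__(self) -> None:
        if not (len(self.spike_onsets) == len(self.spike_durations) == len(self.spike_amplitudes)):
            raise ValueError("spike onset/duration/amplitude lists must have equal lengths")
        if any(d <= 0 for d in self.spike_durations):
            raise ValueError("spike durations must be positive")
        if not (self.fmax > self.fmin > 0):
            raise ValueError("need fmax > fmin > 0")
        if not self.bleach_coeffs[4] < 0:
            raise ValueError("tau_decay must be negative")
        if not self.kd > 0:
            raise ValueError("kd must be positive")
        if self.bleach_mode not in ("multiplicative", "additive"):
            raise ValueError("bleach_mode must be 'multiplicative' or 'additive'")


@dataclass
class ConditionConfig:
    """Population parameters of one experimental condition."""

    name: str
    n_cells: int
    responder_prob: float
    spikes_per_responder_mean: float
    duration_mean: float  # s
    duration_sd: float  # s
    amplitude_mean: float  # nM
    amplitude_sd: float  # nM
    baseline_mean: float  # nM
    baseline_sd: float = 5.0  # nM
    noise_sd: float = 0.2  # a.u.

    def __post_init__(self) -> None:
        if not 0 <= self.responder_prob <= 1:
            raise ValueError("responder_prob must be in [0, 1]")
        for name in ("duration_mean", "amplitude_mean", "baseline_mean",
                     "spikes_per_responder_mean"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be positive")
        if self.n_cells < 1:
            raise ValueError("n_cells must be >= 1")


# Published group statistics of the two flow-onset conditions; per-cell SDs are
# reconstructed from the reported SEMs as SEM * sqrt(n).
SCRAMBLE = ConditionConfig(
    name="scramble", n_cells=347, responder_prob=0.87,
    spikes_per_responder_mean=2.0,
    duration_mean=8.6, duration_sd=0.7 * math.sqrt(347),
    amplitude_mean=4.1, amplitude_sd=0.3 * math.sqrt(347),
    baseline_mean=125.0,
)
KD = ConditionConfig(
    name="kd", n_cells=339, responder_prob=0.94,
    spikes_per_responder_mean=3.0,
    duration_mean=10.7, duration_sd=4.1 * math.sqrt(339),
    amplitude_mean=7.8, amplitude_sd=0.6 * math.sqrt(339),
    baseline_mean=121.0,
)


def condition_preset(name: str, n_cells: int | None = None) -> ConditionConfig:
    presets = {"scramble": SCRAMBLE, "kd": KD}
    try:
        cfg = presets[name]
    except KeyError:
        raise ValueError(f"unknown preset {name!r}; choose from {sorted(presets)}") from None
    return replace(cfg, n_cells=n_cells) if n_cells else replace(cfg)


# ---------------------------------------------------------------------------
# trace synthesis


def _ca_to_f(ca: np.ndarray, fmin: float, fmax: float, kd: float) -> np.ndarray:
    return (fmin * kd + fmax * ca) / (kd + ca)


def true_calcium(truth: TraceGroundTruth, phase_plan: PhasePlan = PhasePlan(),
                 dt: float = 1.0) -> np.ndarray:
    """Noise-free flow-phase Ca(t) in nM (boxcar spikes on the baseline)."""
    n_flow = int(round(phase_plan.flow_s / dt))
    ca = np.full(n_flow, truth.baseline_ca)
    for k, (onset, dur, amp) in enumerate(
        zip(truth.spike_onsets, truth.spike_durations, truth.spike_amplitudes)
    ):
        i0 = int(round(onset / dt))
        n = max(int(round(dur / dt)), 1)
        if i0 < 0 or i0 + n > n_flow:
            raise ValueError(f"spike {k} does not fit inside the flow phase")
        ca[i0 : i0 + n] += amp
    return ca


def _bleach_trend(truth: TraceGroundTruth, t: np.ndarray) -> np.ndarray:
    c0, c1, c2, amp, tau = truth.bleach_coeffs
    return c0 + c1 * t + c2 * t**2 + amp * np.exp(t / tau)


_PHASE_SETTLE_TAU_S = 10.0  # exponential approach of the calibration levels


def synth_trace(truth: TraceGroundTruth, phase_plan: PhasePlan = PhasePlan(),
                dt: float = 1.0) -> CellTrace:
    """Render one cell's full acquisition as a :class:`CellTrace`.

    Raises :class:`SaturationError` when a spike would bring the clean
    fluorescence within a numerical guard of Fmax.
    """
    if not dt > 0:
        raise ValueError("dt must be positive")
    n_flow = int(round(phase_plan.flow_s / dt))
    n_iono = int(round(phase_plan.ionomycin_s / dt))
    n_edta = int(round(phase_plan.edta_s / dt))
    n_total = n_flow + n_iono + n_edta
    t = np.arange(n_total) * dt
    phase = np.array(
        ["flow"] * n_flow + ["ionomycin"] * n_iono + ["edta"] * n_edta, dtype=object
    )

    ca = true_calcium(truth, phase_plan, dt)
    guard = truth.fmax - 1e-6 * (truth.fmax - truth.fmin)
    peaks = _ca_to_f(ca, truth.fmin, truth.fmax, truth.kd)
    if np.any(peaks >= guard):
        bad = [
            k for k, (o, d, a) in enumerate(
                zip(truth.spike_onsets, truth.spike_durations, truth.spike_amplitudes)
            )
            if _ca_to_f(np.array([truth.baseline_ca + a]), truth.fmin, truth.fmax,
                        truth.kd)[0] >= guard
        ]
        raise SaturationError(
            f"saturation: spike(s) {bad} push fluorescence to >= Fmax"
        )

    f_clean = np.empty(n_total)
    f_clean[:n_flow] = peaks
    # ionomycin: exponential approach to Fmax from the last flow level
    rel = np.arange(n_iono) * dt
    f_clean[n_flow : n_flow + n_iono] = truth.fmax - (
        truth.fmax - f_clean[n_flow - 1]
    ) * np.exp(-rel / _PHASE_SETTLE_TAU_S)
    # EDTA: exponential approach to Fmin
    rel = np.arange(n_edta) * dt
    f_clean[n_flow + n_iono :] = truth.fmin + (
        f_clean[n_flow + n_iono - 1] - truth.fmin
    ) * np.exp(-rel / _PHASE_SETTLE_TAU_S)

    trend = _bleach_trend(truth, t)
    if truth.bleach_mode == "multiplicative":
        f = f_clean * (trend / trend[0])
    else:
        f = f_clean + (trend - trend[0])

    if truth.noise_sd > 0:
        rng = np.random.default_rng(truth.seed)
        f = f + rng.normal(0.0, truth.noise_sd, size=n_total)
    return CellTrace(cell_id=truth.seed, t=t, f=f, phase=phase)


def _lognormal(rng: np.random.Generator, mean: float, sd: float, size: int) -> np.ndarray:
    """Lognormal draws with the given arithmetic mean and SD (positive support)."""
    if sd <= 0:
        return np.full(size, mean)
    sigma2 = math.log1p((sd / mean) ** 2)
    mu = math.log(mean) - sigma2 / 2.0
    return rng.lognormal(mu, math.sqrt(sigma2), size=size)


_PLACE_RETRIES = 1000


def _place_spikes(rng, durations_s, flow_s, dt):
    """Non-overlapping spike spans (one clear sample between spikes).

    Longest spikes are placed first into the free gaps of the flow phase; a
    draw that no longer fits is clipped to the largest remaining gap, and
    spikes for which no room remains at all are dropped, so the recorded
    truth always equals what was painted.
    """
    n_flow = int(round(flow_s / dt))
    free = [(2, n_flow - 2)]  # half-open spans of admissible sample indices
    placed: list[tuple[int, int] | None] = [None] * len(durations_s)
    for idx in np.argsort(np.asarray(durations_s))[::-1]:
        if not free:
            continue  # flow phase fully occupied: drop this spike
        n = max(int(round(durations_s[idx] / dt)), 1)
        feasible = [k for k, (lo, hi) in enumerate(free) if hi - lo >= n]
        if feasible:
            weights = np.array([free[k][1] - free[k][0] - n + 1 for k in feasible], float)
            k = feasible[int(rng.choice(len(feasible), p=weights / weights.sum()))]
        else:
            k = max(range(len(free)), key=lambda j: free[j][1] - free[j][0])
            n = free[k][1] - free[k][0]  # clip to the largest remaining gap
        lo, hi = free[k]
        i0 = int(rng.integers(lo, hi - n + 1))
        placed[idx] = (i0, i0 + n)
        free[k : k + 1] = [
            span for span in ((lo, i0 - 1), (i0 + n + 1, hi)) if span[1] - span[0] >= 1
        ]
    kept = [i for i, p in enumerate(placed) if p is not None]
    onsets = [placed[i][0] * dt for i in kept]
    durs = [(placed[i][1] - placed[i][0]) * dt for i in kept]
    return onsets, durs, kept


def synth_condition(
    cfg: ConditionConfig,
    duration: float = 600.0,
    seed: int = 0,
    phase_plan: PhasePlan | None = None,
    dt: float = 1.0,
) -> tuple[list[CellTrace], pd.DataFrame, pd.DataFrame]:
    """Generate a population of traces for one condition.

    Returns (traces, cell_truth, spike_truth).  ``cell_truth`` has one row per
    cell (responder flag, baseline, calibration levels, noise); ``spike_truth``
    one row per true spike including its exact duration, amplitude and the AUC
    a perfect detector would measure (trapezoid of the noiseless trace minus
    its minimum across the spike window).
    """
    if phase_plan is None:
        phase_plan = PhasePlan(flow_s=duration)
    rng = np.random.default_rng(seed)
    traces: list[CellTrace] = []
    cell_rows = []
    spike_rows = []
    for i in range(cfg.n_cells):
        responder = rng.random() < cfg.responder_prob
        if responder:
            n_drawn = 1 + rng.poisson(max(cfg.spikes_per_responder_mean - 1.0, 0.0))
            durs = _lognormal(rng, cfg.duration_mean, cfg.duration_sd, n_drawn)
            amps = _lognormal(rng, cfg.amplitude_mean, cfg.amplitude_sd, n_drawn)
            onsets, durs_q, kept = _place_spikes(rng, durs, phase_plan.flow_s, dt)
            amps = amps[kept]
            n_spikes = len(onsets)
        else:
            n_spikes = 0
            onsets, durs_q, amps = [], [], np.empty(0)
        baseline = max(float(rng.normal(cfg.baseline_mean, cfg.baseline_sd)), 10.0)
        fmin = max(float(rng.normal(100.0, 5.0)), 10.0)
        fmax = fmin + max(float(rng.normal(500.0, 20.0)), 100.0)
        truth = TraceGroundTruth(
            baseline_ca=baseline,
            spike_onsets=tuple(onsets),
            spike_durations=tuple(durs_q),
            spike_amplitudes=tuple(float(a) for a in amps),
            bleach_coeffs=(1.0, -2e-5, -5e-9, 0.03, -150.0),
            noise_sd=cfg.noise_sd,
            fmin=fmin,
            fmax=fmax,
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        trace = synth_trace(truth, phase_plan, dt)
        trace.cell_id = i
        traces.append(trace)

        # local calibration slope: converts fluorescence noise to calcium units
        slope = truth.kd * (fmax - fmin) / (truth.kd + baseline) ** 2
        ca_clean = true_calcium(truth, phase_plan, dt)
        floor = float(ca_clean.min())
        cell_rows.append({
            "cell_id": i, "condition": cfg.name, "responder": bool(n_spikes),
            "n_spikes": int(n_spikes), "baseline_nM": baseline,
            "fmin": fmin, "fmax": fmax, "noise_sd_au": cfg.noise_sd,
            "noise_sd_nM": cfg.noise_sd / slope, "seed": truth.seed,
        })
        for k, (o, d, a) in enumerate(zip(onsets, durs_q, amps)):
            i0 = int(round(o / dt))
            i1 = i0 + int(round(d / dt))
            auc = float(np.trapezoid(ca_clean[i0:i1] - floor, dx=dt))
            spike_rows.append({
                "cell_id": i, "condition": cfg.name, "spike": k, "onset_s": o,
                "duration_s": d, "amplitude_nM": float(a), "auc_nM_s": auc,
            })
    cell_truth = pd.DataFrame(cell_rows)
    spike_cols = ["cell_id", "condition", "spike", "onset_s", "duration_s",
                  "amplitude_nM", "auc_nM_s"]
    spike_truth = pd.DataFrame(spike_rows, columns=spike_cols)
    return traces, cell_truth, spike_truth


# ---------------------------------------------------------------------------
# movie synthesis


def synth_movie(
    labels: CellLabelMap,
    traces: dict[int, CellTrace] | list[CellTrace],
    noise_sd: float = 0.0,
    seed: int = 0,
    background: float = 0.0,
) -> FluorescenceMovie:
    """Paint per-cell traces into frames; per-label noiseless mean equals the trace."""
    if isinstance(traces, list):
        traces = {tr.cell_id: tr for tr in traces}
    ids = labels.cell_ids
    missing = sorted(set(ids.tolist()) - set(traces))
    if missing:
        raise ValueError(f"no trace provided for labels: {missing}")
    lengths = {len(traces[i].f) for i in ids}
    if len(lengths) != 1:
        raise ValueError("all traces must have the same length")
    n_frames = lengths.pop()
    first = traces[int(ids[0])]
    frames = np.full((n_frames,) + labels.labels.shape, background, dtype=float)
    for cid in ids:
        mask = labels.labels == cid
        frames[:, mask] = traces[int(cid)].f[:, None]
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        frames = frames + rng.normal(0.0, noise_sd, size=frames.shape)
    return FluorescenceMovie(frames, dt=first.dt, phase_per_frame=first.phase.copy())


# ---------------------------------------------------------------------------
# monolayer synthesis


@dataclass
class MonolayerSample:
    """Rendered elliptical monolayer with its shape truth and junction raster."""

    labels: CellLabelMap
    truth: pd.DataFrame  # per-cell axes, angle, projected extents, elongation
    junction_image: np.ndarray  # borders with gaps removed
    border_mask: np.ndarray  # full borders (where junction signal belongs)


def _sample_param(rng, spec, size):
    """Scalar -> constant; (mean, sd) -> positive normal draws."""
    if np.isscalar(spec):
        return np.full(size, float(spec))
    mean, sd = spec
    vals = rng.normal(mean, sd, size=size)
    return np.clip(vals, 1e-3, None)


def synth_monolayer(
    n_cells: int,
    elongation: float | tuple[float, float] = 4.0,
    orientation_deg: float | tuple[float, float] = 0.0,
    gap_fraction: float = 0.0,
    seed: int = 0,
    cell_width_px: float = 14.0,
) -> MonolayerSample:
    """Non-overlapping ellipses on a jittered grid, plus a junction raster.

    ``elongation`` is the major/minor full-axis ratio of the drawn ellipse;
    ``orientation_deg`` the major-axis angle from the +x (flow) axis.  The
    junction image paints every inter-cell/background border pixel bright and
    then deletes exactly round(gap_fraction * n_border) randomly chosen border
    pixels, so the uncovered fraction is ``gap_fraction`` by construction.
    """
    if not 0 <= gap_fraction < 1:
        raise ValueError("gap_fraction must be in [0, 1)")
    rng = np.random.default_rng(seed)
    elong = _sample_param(rng, elongation, n_cells)
    angles = np.asarray(
        _sample_param(rng, orientation_deg, n_cells)
        if not np.isscalar(orientation_deg)
        else np.full(n_cells, float(orientation_deg))
    )
    b_semi = cell_width_px / 2.0
    a_semi = elong * b_semi
    box = int(np.ceil(2 * a_semi.max() + 6))
    n_cols = int(np.ceil(np.sqrt(n_cells)))
    n_rows = int(np.ceil(n_cells / n_cols))
    shape = (n_rows * box, n_cols * box)
    labels = np.zeros(shape, dtype=np.int32)
    rows = []
    for i in range(n_cells):
        gr, gc = divmod(i, n_cols)
        placed = False
        for _ in range(_PLACE_RETRIES):
            cy = gr * box + box / 2 + rng.uniform(-2, 2)
            cx = gc * box + box / 2 + rng.uniform(-2, 2)
            theta = math.radians(angles[i])
            # skimage rotation is about the row axis; negate for x/y convention
            rr, cc = skdraw.ellipse(
                cy, cx, b_semi, a_semi[i], shape=shape, rotation=-theta
            )
            if rr.size and np.all(labels[rr, cc] == 0):
                half_y = max(abs(rr - cy).max(), 0.5)
                half_x = max(abs(cc - cx).max(), 0.5)
                if half_y < box / 2 - 1 and half_x < box / 2 - 1:
                    labels[rr, cc] = i + 1
                    placed = True
                    break
        if not placed:
            raise RuntimeError(f"could not place cell {i} without overlap")
        ext_x = 2 * math.hypot(a_semi[i] * math.cos(theta), b_semi * math.sin(theta))
        ext_y = 2 * math.hypot(a_semi[i] * math.sin(theta), b_semi * math.cos(theta))
        rows.append({
            "cell_id": i + 1, "centroid_x": cx, "centroid_y": cy,
            "semi_major_px": float(a_semi[i]), "semi_minor_px": b_semi,
            "orientation_deg": float(abs(((angles[i] + 90) % 180) - 90)),
            "extent_x_px": ext_x, "extent_y_px": ext_y,
            "elongation_factor": ext_x / ext_y,
            "axis_ratio": float(a_semi[i] / b_semi),
        })
    border = find_boundaries(labels, mode="inner") & (labels > 0)
    junction = np.where(border, 200.0, 10.0)
    idx = np.flatnonzero(border.ravel())
    n_gaps = int(round(gap_fraction * idx.size))
    if n_gaps:
        drop = rng.choice(idx, size=n_gaps, replace=False)
        junction.ravel()[drop] = 10.0
    return MonolayerSample(
        labels=CellLabelMap(labels),
        truth=pd.DataFrame(rows),
        junction_image=junction,
        border_mask=border,
    )


# ---------------------------------------------------------------------------
# polarization kinetics


def synth_polar_series(
    tau_min: float,
    timepoints: np.ndarray,
    n_cells: int = 116,
    noise: float = 0.0,
    seed: int = 0,
    d0: float = 0.25,
    d_inf: float = 0.75,
) -> tuple[pd.DataFrame, dict]:
    """Downstream-fraction relaxation d(t) = d_inf - (d_inf - d0)*exp(-t/tau).

    Per-cell values get Gaussian noise of SD ``noise`` (clipped to [0, 1]);
    the returned frame holds per-cell rows plus the per-timepoint mean series
    commonly fed to the exponential fit.  Truth records tau (minutes), d0 and
    d_inf.
    """
    if not tau_min > 0:
        raise ValueError("tau_min must be positive")
    timepoints = np.asarray(timepoints, dtype=float)
    if timepoints.size < 3:
        raise ValueError("need at least 3 timepoints")
    rng = np.random.default_rng(seed)
    ideal = d_inf - (d_inf - d0) * np.exp(-timepoints / tau_min)
    rows = []
    for cell in range(n_cells):
        vals = ideal + (rng.normal(0.0, noise, size=timepoints.size) if noise > 0 else 0.0)
        vals = np.clip(vals, 0.0, 1.0)
        for t, v in zip(timepoints, vals):
            rows.append({"cell_id": cell, "time_min": t, "downstream_fraction": v})
    frame = pd.DataFrame(rows)
    truth = {"tau_min": tau_min, "d0": d0, "d_inf": d_inf}
    return frame, truth


# ---------------------------------------------------------------------------
# velocity fields


def synth_velocity_field(
    flow_rate: float,  # Q, cm^3/s
    width: float,  # b, cm (chamber / voxel width)
    height: float,  # h, cm (chamber height)
    grid: tuple[int, int] = (16, 16),
    viscosity: float = 0.0078,  # dyn*s/cm^2
) -> tuple[VelocityField, ShearMap]:
    """Uniform parallel-plate field with its analytic wall-shear truth.

    The depth-averaged speed is Q/(b*h) everywhere on the grid; the paired
    truth is tau_w = 6*mu*Q/(b*h^2) on every voxel.
    """
    if min(flow_rate, width, height, viscosity) <= 0:
        raise ValueError("flow rate, geometry and viscosity must be positive")
    speed = flow_rate / (width * height)
    vx = np.full(grid, speed)
    vy = np.zeros(grid)
    field = VelocityField(vx=vx, vy=vy, b=width, h=height, units="cm/s")
    tau = np.full(grid, 6.0 * viscosity * flow_rate / (width * height**2))
    return field, ShearMap(tau=tau, mu=viscosity)
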