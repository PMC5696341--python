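"""Pipeline orchestration: traces -> bleach correction -> calibration -> spikes -> stats.

The stage order is fixed (bleach correction precedes calibration, as the
acquisition protocol requires: the calibration phases are recorded after the
flow phase whose trend is removed).  Per-cell failures are recorded and the
run continues; a report is only fatal when it contains no usable cells.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats as sstats

from . import __version__
from .bleach import DEFAULT_ALPHA, detrend, fit_bleach_model, select_alpha
from .calibration import OGB1_KD_NM, CalciumTrace, calibrate, estimate_constants
from .segmentation import CellTrace
from .spikes import (
    Spike,
    SpikeConfig,
    compare_groups,
    detect_spikes,
    estimate_noise,
    summarize_cell,
)
from .synth import ConditionConfig, condition_preset, synth_condition

__all__ = [
    "RunConfig",
    "AnalysisReport",
    "process_trace",
    "run_calcium_pipeline",
    "welch_t_test",
    "render_report",
    "report_hash",
]

logger = logging.getLogger(__name__)

COMPARED_METRICS = ("mean_amplitude", "mean_duration", "mean_auc", "n_spikes")


@dataclass
class RunConfig:
    """Configuration of a calcium-pipeline run.

    Either ``conditions`` names generator presets (or carries full
    :class:`ConditionConfig` objects), or ``trace_files`` points at trace CSVs
    (one per condition).  Every stochastic stage derives its seed from
    ``seed``; the config is serialized verbatim into the report.
    """

    conditions: tuple = ("scramble", "kd")
    n_cells: int | None = None
    seed: int = 0
    alpha: float = DEFAULT_ALPHA
    auto_alpha: bool = False
    kd: float = OGB1_KD_NM
    spike: SpikeConfig = field(default_factory=SpikeConfig)
    flow_axis: tuple[float, float] = (1.0, 0.0)
    trace_files: tuple = ()
    outdir: str | None = None

    def to_dict(self) -> dict:
        d = asdict(self)
        d["conditions"] = [
            c if isinstance(c, str) else asdict(c) for c in self.conditions
        ]
        return d


@dataclass
class AnalysisReport:
    cell_table: pd.DataFrame
    spike_table: pd.DataFrame
    comparisons: dict
    config: dict
    errors: list = field(default_factory=list)
    provenance: dict = field(default_factory=dict)

    @property
    def n_failed(self) -> int:
        return len(self.errors)


def process_trace(
    trace: CellTrace,
    alpha: float = DEFAULT_ALPHA,
    auto_alpha: bool = False,
    kd: float = OGB1_KD_NM,
    spike_cfg: SpikeConfig | None = None,
) -> tuple[dict, list[Spike], CalciumTrace]:
    """Run one cell through bleach correction, calibration and spike detection."""
    spike_cfg = spike_cfg or SpikeConfig()
    if auto_alpha:
        alpha = select_alpha(trace)
    model = fit_bleach_model(trace, alpha=alpha)
    corrected = detrend(trace, model)
    constants = estimate_constants(corrected, kd=kd)
    ca = calibrate(corrected, constants)
    baseline, noise_sd = estimate_noise(ca)
    spikes = detect_spikes(ca, spike_cfg, baseline=baseline, noise_sd=noise_sd)
    summary = summarize_cell(trace.cell_id, spikes, baseline, noise_sd)
    row = asdict(summary)
    row.update(
        alpha=alpha, bleach_converged=model.converged,
        fmin=constants.fmin, fmax=constants.fmax,
        pct_clipped=100.0 * float(np.mean(ca.clipped)),
    )
    return row, spikes, ca


def _load_conditions(cfg: RunConfig) -> dict[str, list[CellTrace]]:
    from .io import read_traces_csv

    groups: dict[str, list[CellTrace]] = {}
    if cfg.trace_files:
        for path in cfg.trace_files:
            groups[Path(path).stem] = read_traces_csv(path)
        return groups
    seeds = np.random.SeedSequence(cfg.seed).generate_state(len(cfg.conditions)) % (2**31)
    for cond, sub_seed in zip(cfg.conditions, seeds):
        c = condition_preset(cond, cfg.n_cells) if isinstance(cond, str) else cond
        traces, _, _ = synth_condition(c, seed=int(sub_seed))
        groups[c.name if isinstance(c, ConditionConfig) else cond] = traces
    return groups


def run_calcium_pipeline(cfg: RunConfig) -> AnalysisReport:
    """Execute the full trace pipeline and group comparisons for a run config."""
    groups = _load_conditions(cfg)
    cell_rows, spike_rows, errors = [], [], []
    for cond, traces in groups.items():
        for trace in traces:
            try:
                row, spikes, _ = process_trace(
                    trace, alpha=cfg.alpha, auto_alpha=cfg.auto_alpha,
                    kd=cfg.kd, spike_cfg=cfg.spike,
                )
            except Exception as exc:  # per-cell failure: record and continue
                errors.append({"condition": cond, "cell_id": trace.cell_id,
                               "error": str(exc)})
                continue
            row["condition"] = cond
            cell_rows.append(row)
            for sp in spikes:
                spike_rows.append({
                    "condition": cond, "cell_id": trace.cell_id,
                    "start_s": sp.start, "end_s": sp.end, "duration_s": sp.duration,
                    "amplitude_nM": sp.amplitude, "auc_nM_s": sp.auc,
                })
    if not cell_rows:
        raise RuntimeError("no cell produced a usable result")
    cell_table = pd.DataFrame(cell_rows)
    spike_table = pd.DataFrame(
        spike_rows,
        columns=["condition", "cell_id", "start_s", "end_s", "duration_s",
                 "amplitude_nM", "auc_nM_s"],
    )
    comparisons = {}
    names = list(groups)
    if len(names) == 2:
        a = cell_table[cell_table.condition == names[0]]
        b = cell_table[cell_table.condition == names[1]]
        for metric in COMPARED_METRICS:
            try:
                mw = compare_groups(a[metric], b[metric])
                t, dof, p_t = welch_t_test(
                    a[metric].dropna(), b[metric].dropna()
                )
            except ValueError as exc:
                comparisons[metric] = {"skipped": str(exc)}
                continue
            comparisons[metric] = {
                "mann_whitney": asdict(mw),
                "welch_t": {"t": t, "dof": dof, "p_two_sided": p_t},
                "mean_a": float(a[metric].mean()), "mean_b": float(b[metric].mean()),
                "groups": names,
            }
        resp = {n: float(cell_table[cell_table.condition == n].responder.mean())
                for n in names}
        comparisons["responder_fraction"] = resp
    report = AnalysisReport(
        cell_table=cell_table,
        spike_table=spike_table,
        comparisons=comparisons,
        config=cfg.to_dict(),
        errors=errors,
        provenance={"package": "endoflow", "version": __version__, "seed": cfg.seed},
    )
    logger.info(
        "pipeline: %d cells analysed, %d failed (alpha=%s, sd_multiplier=%s, "
        "min_duration=%s s, kd=%s nM, flow_axis=%s)",
        len(cell_table), len(errors), cfg.alpha, cfg.spike.sd_multiplier,
        cfg.spike.min_duration, cfg.kd, cfg.flow_axis,
    )
    return report


def welch_t_test(a, b) -> tuple[float, float, float]:
    """Welch's unequal-variance t-test; returns (t, dof, p_two_sided).

    Two zero-variance groups with equal means are a degenerate case and
    return p = 1.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("need at least 2 values per group")
    if a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
        if a.mean() == b.mean():
            return 0.0, float(a.size + b.size - 2), 1.0
        return float("inf"), float(a.size + b.size - 2), 0.0
    res = sstats.ttest_ind(a, b, equal_var=False)
    return float(res.statistic), float(res.df), float(res.pvalue)


def report_hash(report: AnalysisReport) -> str:
    """Deterministic digest over tables, comparisons and config."""
    h = hashlib.sha256()
    h.update(report.cell_table.to_csv(index=False).encode())
    h.update(report.spike_table.to_csv(index=False).encode())
    h.update(json.dumps(report.comparisons, sort_keys=True, default=str).encode())
    h.update(json.dumps(report.config, sort_keys=True, default=str).encode())
    return h.hexdigest()


def render_report(report: AnalysisReport, outdir, plots: bool = False) -> list[Path]:
    """Write CSV tables + JSON summary (and optional plots); returns the paths."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    paths = []
    p = out / "cells.csv"
    report.cell_table.to_csv(p, index=False)
    paths.append(p)
    p = out / "spikes.csv"
    report.spike_table.to_csv(p, index=False)
    paths.append(p)
    summary = {
        "comparisons": report.comparisons,
        "config": report.config,
        "provenance": report.provenance,
        "errors": report.errors,
        "report_hash": report_hash(report),
    }
    p = out / "summary.json"
    p.write_text(json.dumps(summary, indent=2, sort_keys=True, default=str))
    paths.append(p)
    if plots:
        paths.extend(_plot_report(report, out))
    return paths


def _plot_report(report: AnalysisReport, out: Path) -> list[Path]:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    paths = []
    fig, ax = plt.subplots(figsize=(5, 3.2))
    for cond, grp in report.cell_table.groupby("condition"):
        vals = grp["mean_amplitude"].dropna()
        if len(vals):
            ax.hist(vals, bins=30, alpha=0.6, label=str(cond))
    ax.set_xlabel("mean spike amplitude (nM)")
    ax.set_ylabel("cells")
    ax.legend()
    fig.tight_layout()
    p = out / "amplitude_hist.png"
    fig.savefig(p, dpi=120)
    plt.close(fig)
    paths.append(p)
    return paths
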