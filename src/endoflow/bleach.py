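"""Photobleach-trend fitting and removal with an asymmetric loss.

Slow photobleaching is modelled as a second-degree polynomial plus an
exponential decay,

    trend(t) = c0 + c1*t + c2*t**2 + amp * exp(t / tau),

with the linear coefficient ``c1`` and the exponential characteristic time
``tau`` both constrained to negative values (so the exponential term decays).
Because calcium spikes are wide upward excursions that occupy a sizeable part
of the recording, an ordinary least-squares fit would be dragged upward by
them.  The fit therefore minimises the asymmetric loss

    L(y, yhat) = (y - yhat)**2 * (sign(y - yhat) + alpha)**4

where ``y`` is the model prediction and ``yhat`` the measurement: with
0 < alpha < 1 an overestimate (trend above the data) costs a factor
((1+alpha)/(1-alpha))**4 more than the same-sized underestimate, so the trend
hugs the baseline underneath the spikes.  ``alpha`` is a per-trace
meta-parameter; 0.8 is a good default for most traces.  An L2 penalty on the
second-degree coefficient stabilises the fit.  Optimisation is
Levenberg-Marquardt (lmfit).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import lmfit
import numpy as np

from .segmentation import CellTrace

__all__ = [
    "DEFAULT_ALPHA",
    "DEFAULT_ALPHA_GRID",
    "BleachModel",
    "asymmetric_loss",
    "fit_bleach_model",
    "fit_trend_least_squares",
    "select_alpha",
    "detrend",
]

logger = logging.getLogger(__name__)

DEFAULT_ALPHA = 0.8
DEFAULT_ALPHA_GRID = tuple(np.round(np.arange(0.2, 2.01, 0.2), 10))

_MIN_SAMPLES = 20
_TAU_CEIL = -1e-6  # tau strictly negative


@dataclass
class BleachModel:
    """Fitted bleaching trend and the fit's meta-parameters."""

    c0: float
    c1: float
    c2: float
    amp: float
    tau: float
    alpha: float
    l2_lambda: float
    converged: bool = True
    loss_value: float = float("nan")

    def __post_init__(self) -> None:
        if self.c1 > 0:
            raise ValueError("c1 (linear coefficient) must be <= 0")
        if self.tau >= 0:
            raise ValueError("tau must be negative (decaying exponential)")
        if not self.alpha > 0:
            raise ValueError("alpha must be positive")

    def trend(self, t: np.ndarray) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        return self.c0 + self.c1 * t + self.c2 * t**2 + self.amp * np.exp(t / self.tau)


def asymmetric_loss(residual: np.ndarray, alpha: float) -> np.ndarray:
    """Per-sample loss r**2 * (sign(r) + alpha)**4 with r = predicted - measured."""
    if not alpha > 0:
        raise ValueError("alpha must be positive")
    r = np.asarray(residual, dtype=float)
    return r**2 * (np.sign(r) + alpha) ** 4


def _flow_samples(trace: CellTrace) -> tuple[np.ndarray, np.ndarray]:
    mask = trace.phase_mask("flow")
    t, f = trace.t[mask], trace.f[mask]
    if t.size < _MIN_SAMPLES:
        raise ValueError(f"need at least {_MIN_SAMPLES} flow-phase samples, got {t.size}")
    if not np.all(np.isfinite(f)):
        raise ValueError("trace contains non-finite values")
    return t, f


def _make_params(t: np.ndarray, f: np.ndarray, init: dict | None) -> lmfit.Parameters:
    span = float(t[-1] - t[0]) or 1.0
    med = float(np.median(f))
    defaults = {
        "c0": med,
        "c1": 0.0,
        "c2": 0.0,
        "amp": float(f[0] - med),
        "tau": -span / 3.0,
    }
    if init:
        defaults.update(init)
    p = lmfit.Parameters()
    p.add("c0", value=defaults["c0"])
    p.add("c1", value=min(defaults["c1"], 0.0), max=0.0)
    p.add("c2", value=defaults["c2"])
    p.add("amp", value=defaults["amp"])
    p.add("tau", value=min(defaults["tau"], _TAU_CEIL), max=_TAU_CEIL)
    return p


def _trend_of(params, t: np.ndarray) -> np.ndarray:
    v = params.valuesdict()
    return v["c0"] + v["c1"] * t + v["c2"] * t**2 + v["amp"] * np.exp(t / v["tau"])


def _fit(t, f, weight_fn, l2_lambda: float, init: dict | None) -> lmfit.minimizer.MinimizerResult:
    params = _make_params(t, f, init)
    sqrt_l2 = np.sqrt(l2_lambda)

    def residual(p):
        r = _trend_of(p, t) - f  # predicted - measured
        return np.append(weight_fn(r), sqrt_l2 * p["c2"].value)

    return lmfit.minimize(residual, params, method="leastsq", max_nfev=20000)


def _converged(res) -> bool:
    # MINPACK ier 1-4 = converged; 6-8 = requested tolerance below machine
    # precision, i.e. already at the optimum (only error bars unavailable)
    return bool(res.success) or getattr(res, "ier", 0) in (6, 7, 8)


def _default_l2(f: np.ndarray) -> float:
    rng = float(f.max() - f.min())
    return 1e-6 * rng if rng > 0 else 1e-6


def fit_bleach_model(
    trace: CellTrace,
    alpha: float = DEFAULT_ALPHA,
    l2_lambda: float | None = None,
    init: dict | None = None,
) -> BleachModel:
    """Fit the bleaching trend to the flow phase of ``trace``.

    Minimises sum_i L(trend(t_i), F(t_i)) + l2_lambda * c2**2 by
    Levenberg-Marquardt with c1 <= 0 and tau < 0.  Deterministic given the
    initial values.  On non-convergence the best model found is returned
    with ``converged=False`` and a warning is logged.
    """
    if not alpha > 0:
        raise ValueError("alpha must be positive")
    t, f = _flow_samples(trace)
    if l2_lambda is None:
        l2_lambda = _default_l2(f)

    def weights(r):
        return r * (np.sign(r) + alpha) ** 2  # squared -> r^2 (sign(r)+alpha)^4

    res = _fit(t, f, weights, l2_lambda, init)
    ok = _converged(res)
    if not ok:
        logger.warning("bleach fit did not converge: %s", res.message)
    v = res.params.valuesdict()
    return BleachModel(
        c0=v["c0"], c1=min(v["c1"], 0.0), c2=v["c2"], amp=v["amp"],
        tau=min(v["tau"], _TAU_CEIL), alpha=alpha, l2_lambda=l2_lambda,
        converged=ok, loss_value=float(np.sum(res.residual**2)),
    )


def fit_trend_least_squares(
    trace: CellTrace, l2_lambda: float | None = None, init: dict | None = None
) -> BleachModel:
    """Symmetric (ordinary least squares) reference fit of the same trend family.

    Used to quantify what the asymmetric loss buys: on spiked traces this fit
    is biased upward by the spikes.  Reported with ``alpha=nan`` semantics via
    a sentinel alpha of 1.0 stored on the model but a plain residual in the fit.
    """
    t, f = _flow_samples(trace)
    if l2_lambda is None:
        l2_lambda = _default_l2(f)
    res = _fit(t, f, lambda r: r, l2_lambda, init)
    v = res.params.valuesdict()
    return BleachModel(
        c0=v["c0"], c1=min(v["c1"], 0.0), c2=v["c2"], amp=v["amp"],
        tau=min(v["tau"], _TAU_CEIL), alpha=1.0, l2_lambda=l2_lambda,
        converged=_converged(res), loss_value=float(np.sum(res.residual**2)),
    )


def select_alpha(
    trace: CellTrace,
    alpha_grid: tuple[float, ...] = DEFAULT_ALPHA_GRID,
    l2_lambda: float | None = None,
) -> float:
    """Pick alpha from a grid by baseline fidelity.

    For each candidate the trend is fitted and the criterion
    |median(F - trend)| over the sub-median samples (F <= median(F)) is
    evaluated; the sub-median samples are dominated by baseline, so a trend
    that tracks the baseline rather than the spikes scores near zero.  The
    grid value with the smallest criterion wins; near-ties (criterion flat to
    within optimizer precision, 1e-4 of the trace range) fall back to 0.8
    when it is on the grid, otherwise to the smallest tied value.
    """
    grid = tuple(alpha_grid)
    if len(grid) == 0 or any(a <= 0 for a in grid):
        raise ValueError("alpha_grid must be non-empty with positive values")
    t, f = _flow_samples(trace)
    med = np.median(f)
    sub = f <= med
    scores = []
    for a in grid:
        model = fit_bleach_model(trace, alpha=a, l2_lambda=l2_lambda)
        resid = f[sub] - model.trend(t[sub])
        scores.append(abs(float(np.median(resid))))
    scores = np.asarray(scores)
    tol = 1e-4 * max(float(f.max() - f.min()), 1.0)
    tied = np.flatnonzero(scores <= scores.min() + tol)
    tied_alphas = [grid[i] for i in tied]
    for a in tied_alphas:
        if abs(a - DEFAULT_ALPHA) < 1e-12:
            return DEFAULT_ALPHA
    return float(min(tied_alphas))


def detrend(trace: CellTrace, model: BleachModel) -> CellTrace:
    """Subtract the fitted trend from the flow phase, re-anchored for calibration.

    F_corr(t) = F(t) - trend(t) + trend(t_last_flow) on flow samples; the
    ionomycin/EDTA phases are left untouched (they are level estimates, not
    kinetic data).  Re-anchoring at the last flow-phase trend value keeps the
    corrected flow phase continuous with the subsequently recorded
    calibration phases, so per-cell Fmin/Fmax remain commensurable with it.
    """
    mask = trace.phase_mask("flow")
    if not mask.any():
        raise ValueError("trace has no flow phase")
    t_flow = trace.t[mask]
    anchor = float(model.trend(np.array([t_flow[-1]]))[0])
    f = trace.f.copy()
    f[mask] = trace.f[mask] - model.trend(t_flow) + anchor
    return trace.copy_with(f)
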