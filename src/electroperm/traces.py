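"""Dye-uptake and spheroid-area time-course analysis.

After a permeabilizing pulse train, uptake of a membrane-impermeant dye
(YO-PRO-1) rises and saturates as the membrane reseals; the mean trace is
well described by a single-phase exponential

    F(t) = A * (1 - exp(-(t - t0) / tau))   for t >= t0,  0 before,

where ``A`` is the plateau fluorescence (total uptake) and ``tau`` the
resealing time constant.  This module provides baseline handling, the
exponential fit, AUC and fold-change summaries, and percent-area-change
quantification of post-pulse osmotic swelling of spheroids.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import curve_fit

__all__ = [
    "FluorescenceTrace",
    "ExponentialUptakeFit",
    "subtract_baseline",
    "fit_uptake",
    "fit_group_mean",
    "trace_auc",
    "final_uptake",
    "group_fold_change",
    "percent_area_change",
]

TAU_BOUNDS = (1.0, 1e4)  # s; search range for the resealing time constant
MAX_RESTARTS = 5


@dataclass(frozen=True)
class FluorescenceTrace:
    """One time-stamped uptake (or projected-area) series.

    ``times`` must be strictly increasing with at least 3 samples before
    ``exposure_time`` and at least 10 after.  ``meta`` carries grouping
    labels (trace_id, cell_line, ca_mM, field_level, replicate_id, kind).
    """

    times: np.ndarray
    values: np.ndarray
    exposure_time: float
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "values", v)
        if t.ndim != 1 or v.shape != t.shape:
            raise ValueError("times and values must be 1-D arrays of equal length")
        if not np.all(np.diff(t) > 0):
            raise ValueError("times must be strictly increasing")
        if not np.all(np.isfinite(v)):
            raise ValueError("values must be finite")
        if np.sum(t < self.exposure_time) < 3:
            raise ValueError("need >= 3 samples before exposure_time")
        if np.sum(t >= self.exposure_time) < 10:
            raise ValueError("need >= 10 samples after exposure_time")

    @property
    def kind(self) -> str:
        return self.meta.get("kind", "uptake")

    def pre_mask(self) -> np.ndarray:
        return self.times < self.exposure_time

    def baseline(self) -> float:
        """Mean of the pre-exposure samples."""
        return float(np.mean(self.values[self.pre_mask()]))

    def value_at(self, t_eval: float) -> float:
        """Value at the sample nearest ``t_eval`` (within one interval)."""
        idx = int(np.argmin(np.abs(self.times - t_eval)))
        dt = float(np.median(np.diff(self.times)))
        if abs(self.times[idx] - t_eval) > dt:
            raise ValueError(f"t_eval={t_eval} is farther than one sampling interval from data")
        return float(self.values[idx])


@dataclass(frozen=True)
class ExponentialUptakeFit:
    """Result of the single-phase exponential uptake fit."""

    amplitude: float
    tau_reseal: float
    t0: float
    r_squared: float
    converged: bool
    note: str = ""

    def predict(self, t) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        out = np.zeros_like(t)
        post = t >= self.t0
        if math.isfinite(self.tau_reseal):
            out[post] = self.amplitude * -np.expm1(-(t[post] - self.t0) / self.tau_reseal)
        return out


def subtract_baseline(trace: FluorescenceTrace) -> FluorescenceTrace:
    """Subtract the mean pre-exposure value from the whole trace.

    Idempotent: the pre-exposure mean of the output is zero.
    """
    return replace(trace, values=trace.values - trace.baseline())


def _model(t, a, tau, t0):
    return a * -np.expm1(-(t - t0) / tau)


def _r_squared(y: np.ndarray, yhat: np.ndarray) -> float:
    ss_res = float(np.sum((y - yhat) ** 2))
    ss_tot = float(np.sum((y - np.mean(y)) ** 2))
    if ss_tot == 0.0:
        return 1.0 if ss_res == 0.0 else -np.inf
    return 1.0 - ss_res / ss_tot


def fit_uptake(trace: FluorescenceTrace, rng: np.random.Generator | None = None) -> ExponentialUptakeFit:
    """Fit F(t) = A(1 - exp(-(t - t0)/tau)) to the post-exposure samples.

    ``t0`` is fixed at the recorded exposure time (the pulse delivery time is
    known), leaving a 2-parameter bounded nonlinear least-squares problem:
    tau in [1, 1e4] s, A in [0, 10 max(F)].  Initialization: A0 = last value,
    tau0 = time to reach (1 - 1/e) A0; up to 5 jittered restarts.  The trace
    is expected to be baseline-subtracted.  R^2 is computed over the fitted
    (post-exposure) samples.
    """
    t0 = trace.exposure_time
    post = trace.times >= t0
    t = trace.times[post]
    y = trace.values[post]

    if np.allclose(y, 0.0):
        return ExponentialUptakeFit(0.0, math.nan, t0, 1.0, True, "zero amplitude; tau unidentifiable")

    a_hi = 10.0 * float(np.max(y))
    if a_hi <= 0:  # negative-trending trace: the saturating model cannot apply
        return ExponentialUptakeFit(0.0, math.nan, t0, -np.inf, False, "negative-trending trace")

    a0 = float(np.clip(y[-1], a_hi * 1e-6, a_hi))
    target = (1.0 - 1.0 / math.e) * a0
    crossed = np.nonzero(y >= target)[0]
    tau0 = float(t[crossed[0]] - t0) if crossed.size else float((t[-1] - t0) / 3.0)
    tau0 = float(np.clip(tau0, *TAU_BOUNDS))

    rng = rng or np.random.default_rng(0)
    best = None
    for attempt in range(MAX_RESTARTS):
        if attempt == 0:
            p0 = (a0, tau0)
        else:
            p0 = (
                float(np.clip(a0 * rng.lognormal(0, 0.5), a_hi * 1e-6, a_hi)),
                float(np.clip(tau0 * rng.lognormal(0, 0.8), *TAU_BOUNDS)),
            )
        try:
            popt, _ = curve_fit(
                lambda tt, a, tau: _model(tt, a, tau, t0),
                t,
                y,
                p0=p0,
                bounds=([0.0, TAU_BOUNDS[0]], [a_hi, TAU_BOUNDS[1]]),
                maxfev=10000,
            )
        except RuntimeError:
            continue
        resid = float(np.sum((y - _model(t, *popt, t0)) ** 2))
        if best is None or resid < best[1]:
            best = (popt, resid)
    if best is None:
        return ExponentialUptakeFit(math.nan, math.nan, t0, -np.inf, False, "did not converge")
    (a_fit, tau_fit), _ = best
    r2 = _r_squared(y, _model(t, a_fit, tau_fit, t0))
    return ExponentialUptakeFit(float(a_fit), float(tau_fit), t0, r2, True)


def fit_group_mean(traces: list[FluorescenceTrace]) -> tuple[ExponentialUptakeFit, list[ExponentialUptakeFit]]:
    """Fit the pointwise-mean trace of a group, plus each trace individually.

    Traces must share an exposure time; those on different sampling grids are
    linearly interpolated onto the first trace's grid before averaging.
    Returns ``(mean_fit, per_trace_fits)``.
    """
    if not traces:
        raise ValueError("traces must be non-empty")
    t0s = {t.exposure_time for t in traces}
    if len(t0s) != 1:
        raise ValueError(f"inconsistent exposure times: {sorted(t0s)}")
    grid = traces[0].times
    stacked = np.vstack(
        [
            tr.values if tr.times.shape == grid.shape and np.allclose(tr.times, grid)
            else np.interp(grid, tr.times, tr.values)
            for tr in traces
        ]
    )
    mean_trace = FluorescenceTrace(
        times=grid,
        values=stacked.mean(axis=0),
        exposure_time=traces[0].exposure_time,
        meta={**traces[0].meta, "trace_id": "group_mean"},
    )
    return fit_uptake(mean_trace), [fit_uptake(tr) for tr in traces]


def trace_auc(trace: FluorescenceTrace, t_start: float, t_end: float) -> float:
    """Trapezoidal AUC of the baseline-subtracted trace over [t_start, t_end].

    Endpoints off the sampling grid are linearly interpolated; the integral
    is additive over adjacent intervals.
    """
    if t_start >= t_end:
        raise ValueError("t_start must be < t_end")
    if t_start < trace.times[0] or t_end > trace.times[-1]:
        raise ValueError("[t_start, t_end] must lie within the trace span")
    sub = subtract_baseline(trace)
    inner = (sub.times > t_start) & (sub.times < t_end)
    t = np.concatenate([[t_start], sub.times[inner], [t_end]])
    v = np.concatenate(
        [
            [np.interp(t_start, sub.times, sub.values)],
            sub.values[inner],
            [np.interp(t_end, sub.times, sub.values)],
        ]
    )
    return float(np.trapezoid(v, t))


def final_uptake(trace: FluorescenceTrace, t_eval: float) -> float:
    """Baseline-subtracted value at the sample nearest ``t_eval``."""
    return subtract_baseline(trace).value_at(t_eval)


def group_fold_change(
    group_a: list[FluorescenceTrace],
    group_b: list[FluorescenceTrace],
    t_eval: float,
) -> float:
    """Ratio mean_A / mean_B of baseline-subtracted values at ``t_eval``.

    Raises if the denominator group has a non-positive mean (undefined ratio).
    """
    mean_a = float(np.mean([final_uptake(tr, t_eval) for tr in group_a]))
    mean_b = float(np.mean([final_uptake(tr, t_eval) for tr in group_b]))
    if mean_b <= 0:
        raise ValueError(f"denominator group mean is non-positive ({mean_b:.3g}); ratio undefined")
    return mean_a / mean_b


def percent_area_change(trace: FluorescenceTrace, t_eval: float) -> float:
    """Percent change of projected area at ``t_eval`` vs the pre-exposure mean.

    100 * (area(t_eval) - pre_mean) / pre_mean for a ``kind='area'`` trace.
    """
    if trace.kind != "area":
        raise ValueError("percent_area_change requires a trace of kind='area'")
    pre_mean = trace.baseline()
    if pre_mean <= 0:
        raise ValueError("pre-exposure mean area must be > 0")
    return 100.0 * (trace.value_at(t_eval) - pre_mean) / pre_mean
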