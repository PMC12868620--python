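"""AFM stiffness: Hertz-model Young's modulus and stiffness-decay kinetics.

An AFM cantilever with a spherical tip is pushed into the spheroid surface;
past the contact point the Hertz model for a sphere indenting an elastic
half-space predicts

    F = (4/3) * E / (1 - nu^2) * sqrt(R_tip) * delta^(3/2),

with ``delta`` the indentation and ``E`` the Young's modulus.  Because F is
linear in E for a given contact point, the fit here is a grid search over
candidate contact points with a closed-form least-squares E at each, keeping
the pair with the smallest residual.  A 5x5 force map is reduced to one
representative modulus per spheroid (median), and the post-exposure time
course of normalized moduli is fitted with a single-exponential decay to a
plateau, y(t) = p + (1 - p) exp(-t/tau), y(0) = 1.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq, curve_fit

__all__ = [
    "ForceCurve",
    "HertzFit",
    "StiffnessTimeSeries",
    "DecayFit",
    "hertz_force",
    "preprocess_force_curve",
    "hertz_fit",
    "map_representative",
    "series_from_force_maps",
    "fit_stiffness_decay",
    "solve_decay_from_losses",
]


@dataclass(frozen=True)
class ForceCurve:
    """One AFM approach curve with probe constants.

    ``piezo_displacement`` (m) ascends toward contact; ``deflection`` (m) is
    the cantilever deflection.  Defaults: 0.04 N/m spring constant, 1 um
    sphere tip, incompressible sample (nu = 0.5).
    """

    piezo_displacement: np.ndarray
    deflection: np.ndarray
    spring_constant: float = 0.04
    tip_radius: float = 1.0e-6
    poisson_ratio: float = 0.5
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        z = np.asarray(self.piezo_displacement, dtype=float)
        d = np.asarray(self.deflection, dtype=float)
        object.__setattr__(self, "piezo_displacement", z)
        object.__setattr__(self, "deflection", d)
        if z.ndim != 1 or d.shape != z.shape:
            raise ValueError("displacement and deflection must be 1-D arrays of equal length")
        if not np.all(np.diff(z) > 0):
            raise ValueError("piezo_displacement must be strictly increasing")
        if self.spring_constant <= 0:
            raise ValueError("spring_constant must be > 0")
        if self.tip_radius <= 0:
            raise ValueError("tip_radius must be > 0")
        if not (0.0 <= self.poisson_ratio <= 0.5):
            raise ValueError("poisson_ratio must be in [0, 0.5]")

    @property
    def force(self) -> np.ndarray:
        """Force (N) = deflection x spring constant."""
        return self.deflection * self.spring_constant


@dataclass(frozen=True)
class HertzFit:
    """Hertz-model fit result for one force curve."""

    young_modulus: float
    contact_point: float
    r_squared: float
    converged: bool


@dataclass(frozen=True)
class StiffnessTimeSeries:
    """Representative moduli of one spheroid at post-exposure timepoints.

    ``times`` in minutes post-exposure (ascending); ``moduli`` in Pa;
    ``baseline_modulus`` is the pre-exposure value used for normalization.
    """

    times: np.ndarray
    moduli: np.ndarray
    baseline_modulus: float
    group: str = ""
    ca_mM: float = 0.0

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        m = np.asarray(self.moduli, dtype=float)
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "moduli", m)
        if m.shape != t.shape:
            raise ValueError("times and moduli must have equal length")
        if not np.all(np.diff(t) > 0):
            raise ValueError("times must be ascending")
        if self.baseline_modulus <= 0:
            raise ValueError("baseline modulus must be > 0")

    def normalized(self) -> np.ndarray:
        return self.moduli / self.baseline_modulus


def hertz_force(delta, young_modulus: float, tip_radius: float = 1.0e-6, poisson_ratio: float = 0.5):
    """Hertz force (N) for a spherical indenter at indentation ``delta`` (m)."""
    delta = np.asarray(delta, dtype=float)
    f = (4.0 / 3.0) * young_modulus / (1.0 - poisson_ratio**2) * math.sqrt(tip_radius) * np.clip(delta, 0, None) ** 1.5
    return float(f) if f.ndim == 0 else f


def _estimate_contact(curve: ForceCurve) -> float:
    """Crude contact estimate: first sustained rise above the baseline noise."""
    d = curve.deflection
    n0 = max(5, len(d) // 5)
    base, sd = float(np.mean(d[:n0])), float(np.std(d[:n0]))
    thresh = base + max(3.0 * sd, 1e-12)
    above = np.nonzero(d > thresh)[0]
    idx = int(above[0]) if above.size else int(np.argmax(d > base))
    return float(curve.piezo_displacement[idx])


def preprocess_force_curve(
    curve: ForceCurve, contact_displacement: float | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Reduce a raw approach curve to (indentation, force) past contact.

    force = deflection * k; indentation = (z - z_contact) - deflection.
    Only samples past the contact point (with positive indentation) are
    returned.  If ``contact_displacement`` is None it is estimated from the
    deflection baseline.
    """
    zc = _estimate_contact(curve) if contact_displacement is None else contact_displacement
    z = curve.piezo_displacement
    past = z >= zc
    delta = (z[past] - zc) - curve.deflection[past]
    force = curve.force[past]
    keep = delta > 0
    return delta[keep], force[keep]


def hertz_fit(
    curve: ForceCurve,
    max_candidates: int = 200,
    max_indentation: float | None = None,
) -> HertzFit:
    """Joint contact-point and modulus estimate for one approach curve.

    Grid search over candidate contact points (every sample, subsampled to
    ``max_candidates``); at each, E follows in closed form since the Hertz
    force is linear in E.  The fit range is capped at indentations up to the
    tip radius (the sphere form assumes delta << R_tip).  The (contact, E)
    pair with the smallest residual sum of squares wins; if no candidate
    explains any variance (R^2 <= 0) the fit is flagged non-converged.
    """
    z = curve.piezo_displacement
    n = len(z)
    if n < 20:
        raise ValueError("need >= 20 samples")
    cap = curve.tip_radius if max_indentation is None else max_indentation
    pref = (4.0 / 3.0) / (1.0 - curve.poisson_ratio**2) * math.sqrt(curve.tip_radius)

    # candidates span everything that leaves >= 20 post-contact samples
    idxs = np.unique(np.linspace(0, n - 20, min(max_candidates, n - 19)).astype(int))
    best = (None, np.inf)  # (fit params, ss_res)
    for i in idxs:
        zc = z[i]
        delta, force = preprocess_force_curve(curve, zc)
        sel = delta <= cap
        delta, force = delta[sel], force[sel]
        if len(delta) < 20:
            continue
        x = pref * delta**1.5  # F = E * x
        denom = float(np.dot(x, x))
        if denom == 0.0:
            continue
        e_hat = float(np.dot(force, x)) / denom
        if e_hat <= 0:
            continue
        ss_res = float(np.sum((force - e_hat * x) ** 2))
        if ss_res < best[1]:
            ss_tot = float(np.sum((force - np.mean(force)) ** 2))
            r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else (1.0 if ss_res == 0 else -np.inf)
            best = ((e_hat, zc, r2), ss_res)
    if best[0] is None:
        return HertzFit(math.nan, math.nan, -np.inf, False)
    e_hat, zc, r2 = best[0]
    return HertzFit(e_hat, zc, r2, r2 > 0)


def map_representative(fits: list[HertzFit]) -> float:
    """Representative modulus of a force map: median over converged fits."""
    moduli = [f.young_modulus for f in fits if f.converged]
    if not moduli:
        raise ValueError("no converged fits in the force map")
    return float(np.median(moduli))


@dataclass(frozen=True)
class DecayFit:
    """Single-exponential decay-to-plateau fit of normalized stiffness."""

    plateau_fraction: float
    tau_decay: float  # minutes
    r_squared: float

    def predict(self, t) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        y = self.plateau_fraction + (1.0 - self.plateau_fraction) * np.exp(-t / self.tau_decay)
        return float(y) if y.ndim == 0 else y

    def percent_loss(self, t) -> np.ndarray:
        """Predicted percent loss of initial stiffness at time t (min)."""
        y = self.predict(t)
        return 100.0 * (1.0 - y)


def _decay_model(t, p, tau):
    return p + (1.0 - p) * np.exp(-t / tau)


def fit_stiffness_decay(series: StiffnessTimeSeries) -> DecayFit:
    """Fit y(t) = p + (1-p) exp(-t/tau) to baseline-normalized moduli.

    y(0) = 1 by construction; p is the residual stiffness fraction at long
    times and tau (minutes) the decay constant.  Requires >= 3 timepoints.
    """
    if len(series.times) < 3:
        raise ValueError("need >= 3 timepoints")
    y = series.normalized()
    if np.allclose(y, y[0]):
        # constant series: no decay
        return DecayFit(float(np.clip(y[0], 0, 1)), math.inf, 1.0)
    p0 = (float(np.clip(y[-1], 0, 1)), max(float(series.times[-1]) / 3.0, 1e-3))
    popt, _ = curve_fit(
        _decay_model,
        series.times,
        y,
        p0=p0,
        bounds=([0.0, 1e-6], [1.0, 1e4]),
        maxfev=10000,
    )
    yhat = _decay_model(series.times, *popt)
    ss_res = float(np.sum((y - yhat) ** 2))
    ss_tot = float(np.sum((y - np.mean(y)) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    return DecayFit(float(popt[0]), float(popt[1]), r2)


def series_from_force_maps(
    timepoints_min,
    maps: list[list[ForceCurve]],
    group: str = "",
    ca_mM: float = 0.0,
) -> StiffnessTimeSeries:
    """Full force-map reduction: Hertz fits -> per-map median -> time series.

    ``timepoints_min[0]`` must be 0 and its map is the pre-exposure
    baseline; the returned series holds the post-exposure timepoints with
    the baseline median as ``baseline_modulus``.
    """
    timepoints = np.asarray(timepoints_min, dtype=float)
    if len(maps) != len(timepoints):
        raise ValueError("one force map per timepoint required")
    if timepoints[0] != 0.0:
        raise ValueError("first timepoint must be 0 (pre-exposure baseline)")
    medians = np.array([map_representative([hertz_fit(c) for c in m]) for m in maps])
    return StiffnessTimeSeries(
        times=timepoints[1:],
        moduli=medians[1:],
        baseline_modulus=float(medians[0]),
        group=group,
        ca_mM=ca_mM,
    )


def solve_decay_from_losses(
    loss_a_pct: float, t_a: float, loss_b_pct: float, t_b: float
) -> tuple[float, float]:
    """Solve (p, tau) of y(t) = p + (1-p) exp(-t/tau) from two percent losses.

    Given y(t_a) = 1 - loss_a/100 and y(t_b) = 1 - loss_b/100 (t_a < t_b,
    loss_a < loss_b), returns the unique (plateau_fraction, tau).  Used to
    turn a pair of reported stiffness losses into model parameters.
    """
    if not (0 < loss_a_pct < loss_b_pct < 100):
        raise ValueError("need 0 < loss_a < loss_b < 100")
    if not (0 < t_a < t_b):
        raise ValueError("need 0 < t_a < t_b")
    ya, yb = 1.0 - loss_a_pct / 100.0, 1.0 - loss_b_pct / 100.0

    def resid(tau: float) -> float:
        ua, ub = math.exp(-t_a / tau), math.exp(-t_b / tau)
        p = (ya - ua) / (1.0 - ua)
        return p + (1.0 - p) * ub - yb

    tau = brentq(resid, 1e-3, 1e3, xtol=1e-12, rtol=1e-14)
    ua = math.exp(-t_a / tau)
    p = (ya - ua) / (1.0 - ua)
    return float(p), float(tau)
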