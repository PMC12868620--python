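"""Induced-transmembrane-potential threshold model and electrode field model.

A spherical cell in a uniform external field develops an induced
transmembrane potential (TMP) at its poles given, at steady state, by the
Schwan relation ``dV = (3/2) E R``.  For pulses shorter than a few membrane
charging time constants the TMP only reaches a fraction ``1 - exp(-t/tau)``
of its steady-state value, so the external field required to bring the pole
TMP to the electroporation threshold (~0.2 V) rises steeply at short pulse
durations and falls inversely with cell radius.  This module implements that
charging-corrected threshold model, plus a closed-form two-wire electrode
field model used to assign exposure intensities to imaging sub-regions.

All quantities are SI internally (m, s, V, V/m); helpers convert to the
display units customary in the field (um, kV/cm).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "ThresholdModelParams",
    "SphericalCell",
    "PulseProtocol",
    "ElectrodeGeometry",
    "RoiSpec",
    "steady_state_schwan_field",
    "charging_factor",
    "threshold_field",
    "threshold_curve",
    "two_wire_field_profile",
    "assign_subroi_fields",
    "permeabilized_fraction",
    "v_per_m_to_kv_per_cm",
    "kv_per_cm_to_v_per_m",
]


def v_per_m_to_kv_per_cm(e: float | np.ndarray) -> float | np.ndarray:
    """Convert a field strength from V/m to kV/cm (1 kV/cm = 1e5 V/m)."""
    return np.asarray(e) / 1e5 if np.ndim(e) else e / 1e5


def kv_per_cm_to_v_per_m(e: float | np.ndarray) -> float | np.ndarray:
    """Convert a field strength from kV/cm to V/m."""
    return np.asarray(e) * 1e5 if np.ndim(e) else e * 1e5


@dataclass(frozen=True)
class ThresholdModelParams:
    """Biophysical constants of the electroporation threshold model.

    Parameters
    ----------
    dv_threshold:
        Transmembrane potential (V) at which electroporation is assumed to
        begin; ~0.2 V across many mammalian cell types.
    tau_charge:
        Membrane charging time constant (s); ~2 us for mammalian cells.
    """

    dv_threshold: float = 0.2
    tau_charge: float = 2e-6

    def __post_init__(self) -> None:
        if self.dv_threshold <= 0:
            raise ValueError("dv_threshold must be > 0")
        if self.tau_charge <= 0:
            raise ValueError("tau_charge must be > 0")


@dataclass(frozen=True)
class SphericalCell:
    """A cell idealized as a sphere of given radius (m)."""

    radius: float

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise ValueError("radius must be > 0")

    @classmethod
    def from_diameter_um(cls, diameter_um: float) -> "SphericalCell":
        return cls(radius=diameter_um * 1e-6 / 2.0)


@dataclass(frozen=True)
class PulseProtocol:
    """A train of nearly rectangular nanosecond pulses.

    Defaults mirror the exposure used throughout: 200 pulses of 300 ns at
    10 Hz with 1 kV between the electrodes.
    """

    pulse_duration: float = 300e-9
    n_pulses: int = 200
    frequency: float = 10.0
    amplitude: float = 1000.0

    def __post_init__(self) -> None:
        if self.pulse_duration <= 0:
            raise ValueError("pulse_duration must be > 0")
        if self.n_pulses <= 0:
            raise ValueError("n_pulses must be > 0")
        if self.frequency <= 0:
            raise ValueError("frequency must be > 0")
        if self.amplitude <= 0:
            raise ValueError("amplitude must be > 0")


@dataclass(frozen=True)
class ElectrodeGeometry:
    """Two parallel cylindrical wire electrodes in the imaging plane.

    ``wire_radius`` and ``center_spacing`` are in metres; defaults are the
    0.5 mm tungsten rods at 1.5 mm center-to-center spacing.  The wires lie
    with centers at (+-center_spacing/2, 0).
    """

    wire_radius: float = 0.25e-3
    center_spacing: float = 1.5e-3
    applied_voltage: float = 1.0

    def __post_init__(self) -> None:
        if self.wire_radius <= 0:
            raise ValueError("wire_radius must be > 0")
        if self.center_spacing <= 2 * self.wire_radius:
            raise ValueError("center_spacing must exceed the wire diameter")
        if self.applied_voltage <= 0:
            raise ValueError("applied_voltage must be > 0")

    @property
    def line_charge_offset(self) -> float:
        """Distance s of the equivalent line charges from the midplane."""
        return math.sqrt((self.center_spacing / 2) ** 2 - self.wire_radius**2)

    @property
    def gap_edge(self) -> float:
        """x-coordinate of the inner wire surface (edge of the gap)."""
        return self.center_spacing / 2 - self.wire_radius


@dataclass(frozen=True)
class RoiSpec:
    """The imaging region of interest, split into strips ("sub-ROIs").

    The ROI is a ``roi_width`` x ``roi_depth`` rectangle whose long edge lies
    on the line through the wire centers (y = 0), centered on the midplane,
    extending in +y away from the electrode gap.  It is divided into
    ``n_subrois`` equal strips parallel to that edge; strip 1 is closest to
    the electrodes.  Defaults: 800 x 600 um split into three 800 x 200 um
    strips.
    """

    roi_width: float = 800e-6
    roi_depth: float = 600e-6
    n_subrois: int = 3
    offset_from_gap: float = 0.0

    def __post_init__(self) -> None:
        if self.roi_width <= 0 or self.roi_depth <= 0:
            raise ValueError("roi_width and roi_depth must be > 0")
        if self.n_subrois < 1:
            raise ValueError("n_subrois must be >= 1")
        if self.offset_from_gap < 0:
            raise ValueError("offset_from_gap must be >= 0")


def steady_state_schwan_field(dv: float, cell: SphericalCell) -> float:
    """External field (V/m) inducing pole TMP ``dv`` at steady state.

    E = (2/3) * dv / R, the inverse of the Schwan relation evaluated at the
    electrode-facing pole of a spherical cell.
    """
    if dv <= 0:
        raise ValueError("dv must be > 0")
    return (2.0 / 3.0) * dv / cell.radius


def charging_factor(t: float | np.ndarray, tau_charge: float) -> float | np.ndarray:
    """Fraction of the steady-state TMP reached after time ``t``.

    1 - exp(-t/tau); in [0, 1), monotone increasing in t.
    """
    if tau_charge <= 0:
        raise ValueError("tau_charge must be > 0")
    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr < 0):
        raise ValueError("t must be >= 0")
    out = -np.expm1(-t_arr / tau_charge)
    return float(out) if np.ndim(t) == 0 else out


def threshold_field(
    cell: SphericalCell,
    pulse_duration: float,
    params: ThresholdModelParams = ThresholdModelParams(),
) -> float:
    """Electroporation threshold field (V/m) for a finite-duration pulse.

    The steady-state Schwan threshold divided by the charging factor: short
    pulses leave the membrane only partially charged, so a stronger field is
    needed to push the pole TMP to ``dv_threshold`` within the pulse.
    """
    if pulse_duration <= 0:
        raise ValueError("pulse_duration must be > 0 (charging factor vanishes)")
    f = charging_factor(pulse_duration, params.tau_charge)
    return steady_state_schwan_field(params.dv_threshold, cell) / f


def threshold_curve(
    diameters_um,
    durations_s,
    params: ThresholdModelParams = ThresholdModelParams(),
) -> pd.DataFrame:
    """Threshold field over a (diameter, pulse duration) cross product.

    Returns a tidy table with columns ``diameter_um``, ``pulse_duration_s``,
    ``e_threshold_v_per_m`` and ``e_threshold_kv_per_cm``; for a fixed
    duration the threshold decreases strictly with diameter, and the ratio
    between any two diameters is duration-independent.
    """
    diameters_um = list(diameters_um)
    durations_s = list(durations_s)
    if not diameters_um or not durations_s:
        raise ValueError("diameters and durations must be non-empty")
    rows = []
    for d_um in diameters_um:
        cell = SphericalCell.from_diameter_um(d_um)
        for t in durations_s:
            e = threshold_field(cell, t, params)
            rows.append(
                {
                    "diameter_um": d_um,
                    "pulse_duration_s": t,
                    "e_threshold_v_per_m": e,
                    "e_threshold_kv_per_cm": v_per_m_to_kv_per_cm(e),
                }
            )
    return pd.DataFrame(rows)


def _two_wire_field_vectors(geom: ElectrodeGeometry, pts: np.ndarray) -> np.ndarray:
    """Field vectors (V/m) of the equivalent +-line-charge pair at ``pts``."""
    s = geom.line_charge_offset
    # lambda / (2 pi eps) chosen so the inter-wire potential difference
    # equals applied_voltage: lambda/(pi eps) = U / acosh(d / 2a)
    k = geom.applied_voltage / (2.0 * math.acosh(geom.center_spacing / (2 * geom.wire_radius)))
    pos = np.array([s, 0.0])
    neg = np.array([-s, 0.0])
    rp = pts - pos
    rn = pts - neg
    rp2 = np.sum(rp**2, axis=1, keepdims=True)
    rn2 = np.sum(rn**2, axis=1, keepdims=True)
    return k * (rp / rp2 - rn / rn2)


def _points_inside_wires(geom: ElectrodeGeometry, pts: np.ndarray) -> np.ndarray:
    half = geom.center_spacing / 2
    d1 = np.hypot(pts[:, 0] - half, pts[:, 1])
    d2 = np.hypot(pts[:, 0] + half, pts[:, 1])
    return (d1 <= geom.wire_radius) | (d2 <= geom.wire_radius)


def two_wire_field_profile(geom: ElectrodeGeometry, points) -> np.ndarray:
    """Field magnitude (V/m) of the two-wire electrode pair at planar points.

    Closed-form model: two infinite parallel cylinders at potential
    difference ``applied_voltage`` are electrostatically equivalent to two
    opposite line charges at x = +-s, s = sqrt((d/2)^2 - a^2); the field is
    their superposition.  Linear in the applied voltage and symmetric under
    reflection through the midplane.

    ``points`` is an (N, 2) array-like of (x, y) metres; points inside a
    wire cross-section raise ``ValueError``.
    """
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    if pts.shape[1] != 2:
        raise ValueError("points must be (N, 2) planar coordinates")
    if np.any(_points_inside_wires(geom, pts)):
        raise ValueError("point(s) lie inside an electrode cross-section")
    vec = _two_wire_field_vectors(geom, pts)
    return np.hypot(vec[:, 0], vec[:, 1])


def assign_subroi_fields(
    geom: ElectrodeGeometry,
    roi: RoiSpec = RoiSpec(),
    grid_n: int = 21,
) -> pd.DataFrame:
    """Mean/min/max field per sub-ROI strip, sampled on a uniform grid.

    Each sub-ROI is sampled on a ``grid_n`` x ``grid_n`` Cartesian grid.
    Returns a table with columns ``subroi_index`` (1 = nearest the
    electrodes), ``e_mean``, ``e_min``, ``e_max`` in V/m.
    """
    if grid_n < 2:
        raise ValueError("grid_n must be >= 2")
    half_w = roi.roi_width / 2
    strip = roi.roi_depth / roi.n_subrois
    xs = np.linspace(-half_w, half_w, grid_n)
    rows = []
    for i in range(roi.n_subrois):
        y0 = roi.offset_from_gap + i * strip
        ys = np.linspace(y0, y0 + strip, grid_n)
        gx, gy = np.meshgrid(xs, ys)
        pts = np.column_stack([gx.ravel(), gy.ravel()])
        if np.any(_points_inside_wires(geom, pts)):
            raise ValueError("ROI overlaps an electrode cross-section")
        e = two_wire_field_profile(geom, pts)
        rows.append(
            {
                "subroi_index": i + 1,
                "e_mean": float(np.mean(e)),
                "e_min": float(np.min(e)),
                "e_max": float(np.max(e)),
            }
        )
    return pd.DataFrame(rows)


def permeabilized_fraction(
    radii,
    local_field: float,
    pulse_duration: float,
    params: ThresholdModelParams = ThresholdModelParams(),
) -> float:
    """Fraction of a cell population whose threshold lies below the field.

    Applies the threshold model to each radius and counts cells with
    ``threshold_field <= local_field``; non-decreasing in ``local_field``.
    """
    radii = np.asarray(list(radii), dtype=float)
    if radii.size == 0:
        raise ValueError("radii must be non-empty")
    if np.any(radii <= 0):
        raise ValueError("radii must be > 0")
    if local_field < 0:
        raise ValueError("local_field must be >= 0")
    thresholds = np.array(
        [threshold_field(SphericalCell(r), pulse_duration, params) for r in radii]
    )
    return float(np.mean(thresholds <= local_field))
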