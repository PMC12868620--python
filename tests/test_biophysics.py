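"""Threshold model and two-wire electrode field tests."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from electroperm.biophysics import (
    ElectrodeGeometry,
    RoiSpec,
    SphericalCell,
    ThresholdModelParams,
    assign_subroi_fields,
    charging_factor,
    permeabilized_fraction,
    steady_state_schwan_field,
    threshold_curve,
    threshold_field,
    two_wire_field_profile,
)


class TestSchwanSteadyState:
    @pytest.mark.parametrize(
        "dv, radius_um, expected",
        [(0.2, 10.0, 13333.333333), (0.2, 15.0, 8888.888889)],
    )
    def test_values(self, dv, radius_um, expected):
        e = steady_state_schwan_field(dv, SphericalCell(radius_um * 1e-6))
        assert e == pytest.approx(expected, rel=1e-9)

    def test_homogeneity_and_monotonicity(self):
        cell = SphericalCell(12e-6)
        assert steady_state_schwan_field(0.4, cell) == pytest.approx(
            2 * steady_state_schwan_field(0.2, cell)
        )
        assert steady_state_schwan_field(0.2, SphericalCell(20e-6)) < steady_state_schwan_field(
            0.2, SphericalCell(10e-6)
        )

    @pytest.mark.parametrize("dv, radius", [(0.0, 1e-6), (-1.0, 1e-6)])
    def test_domain_errors(self, dv, radius):
        with pytest.raises(ValueError):
            steady_state_schwan_field(dv, SphericalCell(radius))


class TestChargingFactor:
    def test_limits(self):
        assert charging_factor(0.0, 2e-6) == 0.0
        assert charging_factor(200e-6, 2e-6) == pytest.approx(1.0, abs=1e-12)

    def test_300ns_pulse(self):
        # 1 - exp(-0.15), evaluated independently
        assert charging_factor(300e-9, 2e-6) == pytest.approx(0.139292, abs=5e-7)

    def test_monotone_and_errors(self):
        t = np.linspace(0, 1e-5, 50)
        f = charging_factor(t, 2e-6)
        assert np.all(np.diff(f) > 0)
        with pytest.raises(ValueError):
            charging_factor(-1e-9, 2e-6)


class TestThresholdField:
    def test_size_ratio_is_radius_ratio(self):
        """A 20-um cell needs a 1.5x stronger field than a 30-um cell."""
        small = SphericalCell.from_diameter_um(20)
        large = SphericalCell.from_diameter_um(30)
        for dur in (100e-9, 300e-9, 1e-6, 1e-3):
            ratio = threshold_field(small, dur) / threshold_field(large, dur)
            assert ratio == pytest.approx(1.5, rel=1e-12)

    def test_reference_value(self):
        # 8888.89 / 0.139292 evaluated independently
        e = threshold_field(SphericalCell(15e-6), 300e-9)
        assert e == pytest.approx(6.3815e4, rel=1e-4)

    def test_converges_to_steady_state(self):
        cell = SphericalCell(10e-6)
        params = ThresholdModelParams()
        e_ss = steady_state_schwan_field(params.dv_threshold, cell)
        e_long = threshold_field(cell, 14 * params.tau_charge, params)
        assert abs(e_long - e_ss) / e_ss < 1e-3

    def test_strictly_decreasing_in_duration(self):
        cell = SphericalCell(10e-6)
        durations = np.logspace(-7, -4, 20)
        es = [threshold_field(cell, d) for d in durations]
        assert np.all(np.diff(es) < 0)

    def test_zero_duration_errors(self):
        with pytest.raises(ValueError):
            threshold_field(SphericalCell(10e-6), 0.0)

    @given(
        r1=st.floats(2e-6, 40e-6),
        r2=st.floats(2e-6, 40e-6),
        dur=st.floats(1e-8, 1e-3),
    )
    @settings(deadline=None, max_examples=50)
    def test_ratio_property(self, r1, r2, dur):
        """threshold(R1)/threshold(R2) = R2/R1 exactly, for any duration."""
        ratio = threshold_field(SphericalCell(r1), dur) / threshold_field(SphericalCell(r2), dur)
        assert ratio == pytest.approx(r2 / r1, rel=1e-9)


class TestThresholdCurve:
    def test_consistent_spacing_across_durations(self):
        tbl = threshold_curve([20, 30], [100e-9, 300e-9, 1e-6])
        piv = tbl.pivot(index="pulse_duration_s", columns="diameter_um", values="e_threshold_v_per_m")
        ratios = piv[20] / piv[30]
        assert np.allclose(ratios, 1.5)

    def test_single_cell_consistency_and_linearity(self):
        tbl = threshold_curve([25], [300e-9])
        assert len(tbl) == 1
        assert tbl["e_threshold_v_per_m"].iloc[0] == pytest.approx(
            threshold_field(SphericalCell.from_diameter_um(25), 300e-9)
        )
        doubled = threshold_curve([25], [300e-9], ThresholdModelParams(dv_threshold=0.4))
        assert doubled["e_threshold_v_per_m"].iloc[0] == pytest.approx(
            2 * tbl["e_threshold_v_per_m"].iloc[0]
        )
        assert tbl["e_threshold_kv_per_cm"].iloc[0] == pytest.approx(
            tbl["e_threshold_v_per_m"].iloc[0] / 1e5
        )

    def test_empty_inputs_error(self):
        with pytest.raises(ValueError):
            threshold_curve([], [300e-9])
        with pytest.raises(ValueError):
            threshold_curve([20], [])


def _brute_force_two_wire(geom: ElectrodeGeometry, x: float, y: float) -> float:
    """Independent superposition of the two line-charge fields, plain math."""
    s = math.sqrt((geom.center_spacing / 2) ** 2 - geom.wire_radius**2)
    k = geom.applied_voltage / (2 * math.acosh(geom.center_spacing / (2 * geom.wire_radius)))
    ex = ey = 0.0
    for sign, (cx, cy) in ((+1, (s, 0.0)), (-1, (-s, 0.0))):
        dx, dy = x - cx, y - cy
        r2 = dx * dx + dy * dy
        ex += sign * k * dx / r2
        ey += sign * k * dy / r2
    return math.hypot(ex, ey)


class TestTwoWireField:
    geom = ElectrodeGeometry()

    def test_midpoint_value(self):
        # E_mid = U / (s acosh(d/2a)); s = 0.7071 mm, acosh(3) = 1.7627
        e = two_wire_field_profile(self.geom, [[0.0, 0.0]])[0]
        assert e == pytest.approx(802.3, rel=1e-3)

    def test_matches_brute_force_superposition(self):
        rng = np.random.default_rng(1)
        pts = []
        while len(pts) < 100:
            p = rng.uniform(-3e-3, 3e-3, 2)
            if (
                math.hypot(p[0] - 0.75e-3, p[1]) > 0.3e-3
                and math.hypot(p[0] + 0.75e-3, p[1]) > 0.3e-3
            ):
                pts.append(p)
        pts = np.array(pts)
        mine = two_wire_field_profile(self.geom, pts)
        oracle = np.array([_brute_force_two_wire(self.geom, x, y) for x, y in pts])
        assert np.allclose(mine, oracle, rtol=1e-9)

    def test_mirror_symmetry(self):
        e1 = two_wire_field_profile(self.geom, [[0.3e-3, 0.2e-3]])
        e2 = two_wire_field_profile(self.geom, [[-0.3e-3, 0.2e-3]])
        assert e1[0] == pytest.approx(e2[0], rel=1e-12)

    def test_monotone_decay_along_bisector(self):
        ys = np.linspace(0, 2e-3, 30)
        pts = np.column_stack([np.zeros_like(ys), ys])
        e = two_wire_field_profile(self.geom, pts)
        assert np.all(np.diff(e) < 0)

    def test_voltage_linearity(self):
        geom2 = ElectrodeGeometry(applied_voltage=2.0)
        e1 = two_wire_field_profile(self.geom, [[0.1e-3, 0.4e-3]])
        e2 = two_wire_field_profile(geom2, [[0.1e-3, 0.4e-3]])
        assert e2[0] == pytest.approx(2 * e1[0], rel=1e-12)

    def test_point_inside_wire_errors(self):
        with pytest.raises(ValueError):
            two_wire_field_profile(self.geom, [[0.75e-3, 0.0]])


class TestSubroiFields:
    geom = ElectrodeGeometry()

    def test_means_decay_with_distance(self):
        tbl = assign_subroi_fields(self.geom)
        assert list(tbl["subroi_index"]) == [1, 2, 3]
        assert tbl["e_mean"].is_monotonic_decreasing
        assert (tbl["e_min"] <= tbl["e_mean"]).all() and (tbl["e_mean"] <= tbl["e_max"]).all()

    def test_grid_convergence(self):
        coarse = assign_subroi_fields(self.geom, grid_n=21)
        fine = assign_subroi_fields(self.geom, grid_n=41)
        rel = np.abs(coarse["e_mean"] - fine["e_mean"]) / fine["e_mean"]
        assert (rel < 0.01).all()

    def test_voltage_scaling(self):
        base = assign_subroi_fields(self.geom)
        doubled = assign_subroi_fields(ElectrodeGeometry(applied_voltage=2.0))
        for col in ("e_mean", "e_min", "e_max"):
            assert np.allclose(doubled[col], 2 * base[col])

    def test_roi_overlapping_electrodes_errors(self):
        wide = RoiSpec(roi_width=2.0e-3)
        with pytest.raises(ValueError):
            assign_subroi_fields(self.geom, wide)


class TestPermeabilizedFraction:
    def test_limits(self):
        radii = [10e-6, 15e-6]
        assert permeabilized_fraction(radii, 0.0, 300e-9) == 0.0
        assert permeabilized_fraction([1e-3, 2e-3], 1e4, 300e-9) == 1.0

    def test_midway_field_splits_population(self):
        thr = [threshold_field(SphericalCell(r), 300e-9) for r in (10e-6, 15e-6)]
        mid = sum(thr) / 2
        assert permeabilized_fraction([10e-6, 15e-6], mid, 300e-9) == 0.5

    def test_monotone_in_field(self):
        rng = np.random.default_rng(3)
        radii = rng.uniform(5e-6, 20e-6, 50)
        fields = np.linspace(0, 5e4, 20)
        fr = [permeabilized_fraction(radii, f, 300e-9) for f in fields]
        assert np.all(np.diff(fr) >= 0)

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            permeabilized_fraction([], 1e4, 300e-9)
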