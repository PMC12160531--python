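"""EOA/AVA/TPG/MPG/VTI and plane-based velocity analysis."""

import numpy as np
import pytest

from valvemetrics.hemodynamic_metrics import (PlaneSection, VelocityVolume, ava,
                                              eoa, mpg, plane_flow_rate,
                                              plane_velocity_stats, tpg, vti)
from valvemetrics.synthetic_data import GeneratorSpec, gen_velocity_volume
from valvemetrics.waveforms import UNIT_FLOW, UNIT_PRESSURE, UNIT_VELOCITY, Waveform


def _wave(values, unit, n=None, period=1.0):
    values = np.asarray(values, dtype=float)
    t = np.linspace(0, period, values.size, endpoint=False)
    return Waveform(t, values, period, unit)


class TestEOA:
    def test_constant_flow_and_gradient_closed_form(self):
        n = 64
        Q = _wave(np.full(n, 250.0), UNIT_FLOW)
        dP = _wave(np.full(n, 5.0), UNIT_PRESSURE)
        expected = 250.0 / (51.6 * np.sqrt(5.0 / 1.06))
        assert expected == pytest.approx(2.231, abs=1e-3)
        assert eoa(Q, dP) == pytest.approx(expected, rel=1e-9)

    def test_linear_in_flow(self):
        n = 128
        t = np.linspace(0, 1, n, endpoint=False)
        q = 300 * np.exp(-((t - 0.2) / 0.1) ** 2)
        dp = np.where(t < 0.4, 5.0 * np.sin(np.pi * t / 0.4), -1.0)
        Q, dP = _wave(q, UNIT_FLOW), _wave(dp, UNIT_PRESSURE)
        assert eoa(Q.with_values(2 * q), dP) == pytest.approx(2 * eoa(Q, dP), rel=1e-12)

    def test_inverse_sqrt_in_gradient(self):
        n = 64
        Q = _wave(np.full(n, 250.0), UNIT_FLOW)
        dP = _wave(np.full(n, 5.0), UNIT_PRESSURE)
        dP4 = dP.with_values(4 * dP.values)
        assert eoa(Q, dP4) == pytest.approx(eoa(Q, dP) / 2, rel=1e-12)

    def test_no_positive_window_raises(self):
        n = 64
        Q = _wave(np.full(n, 250.0), UNIT_FLOW)
        dP = _wave(np.full(n, -2.0), UNIT_PRESSURE)
        with pytest.raises(ValueError, match="positive"):
            eoa(Q, dP)

    def test_refinement_invariance(self):
        vals = []
        for n in (128, 512, 2048):
            t = np.linspace(0, 1, n, endpoint=False)
            q = 300 * np.sin(np.pi * np.clip(t, 0, 0.35) / 0.35) * (t < 0.35)
            dp = 6 * np.sin(np.pi * np.clip(t, 0, 0.35) / 0.35) * (t < 0.35) - 0.5 * (t >= 0.35)
            vals.append(eoa(_wave(q, UNIT_FLOW), _wave(dp, UNIT_PRESSURE)))
        assert vals[1] == pytest.approx(vals[2], rel=2e-3)
        assert vals[0] == pytest.approx(vals[2], rel=1e-2)


class TestAVA:
    def test_simple_division(self):
        assert ava(100.0, 50.0) == 2.0

    def test_printed_magnitudes_consistent(self):
        # a 99.48 mL stroke volume with 66.76 cm VTI gives a 1.49 cm^2 valve
        assert ava(99.48, 66.76) == pytest.approx(1.49, abs=5e-3)

    def test_inverse_in_vti(self):
        assert ava(90.0, 30.0) == pytest.approx(2 * ava(90.0, 60.0))

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            ava(0.0, 50.0)
        with pytest.raises(ValueError):
            ava(100.0, -1.0)


class TestTPG:
    def test_constant_difference(self):
        n = 64
        p_lv = _wave(np.full(n, 100.0), UNIT_PRESSURE)
        p_ao = _wave(np.full(n, 95.0), UNIT_PRESSURE)
        assert tpg(p_lv, p_ao, 0.1, 0.4) == pytest.approx(5.0, rel=1e-12)

    def test_antisymmetric_difference_cancels(self):
        n = 256
        t = np.linspace(0, 1, n, endpoint=False)
        diff = np.sin(2 * np.pi * (t - 0.1) / 0.3)  # full period inside window
        p_ao = _wave(np.full(n, 90.0), UNIT_PRESSURE)
        p_lv = p_ao.with_values(p_ao.values + diff)
        assert tpg(p_lv, p_ao, 0.1, 0.4) == pytest.approx(0.0, abs=1e-10)

    def test_half_sine_difference_mean(self):
        n = 20000
        t = np.linspace(0, 1, n, endpoint=False)
        diff = 10.0 * np.sin(np.pi * np.clip(t, 0, 0.3) / 0.3) * (t <= 0.3)
        p_ao = _wave(np.full(n, 90.0), UNIT_PRESSURE)
        p_lv = p_ao.with_values(p_ao.values + diff)
        assert tpg(p_lv, p_ao, 0.0, 0.3) == pytest.approx(20 / np.pi, rel=1e-4)

    def test_swap_negates(self):
        n = 64
        p_lv = _wave(95.0 + np.arange(n) * 0.01, UNIT_PRESSURE)
        p_ao = _wave(np.full(n, 90.0), UNIT_PRESSURE)
        assert tpg(p_ao, p_lv, 0.1, 0.5) == pytest.approx(-tpg(p_lv, p_ao, 0.1, 0.5))


class TestMPG:
    def test_constant_velocity(self):
        v = _wave(np.full(64, 1.0), UNIT_VELOCITY)
        assert mpg(v, (0.0, 0.5)) == pytest.approx(4.0)
        v2 = _wave(np.full(64, 2.0), UNIT_VELOCITY)
        assert mpg(v2, (0.0, 0.5)) == pytest.approx(16.0)

    def test_alternating_velocities_sample_mean(self):
        vals = np.tile([1.0, 2.0], 32)
        v = _wave(vals, UNIT_VELOCITY)
        # (4*1 + 4*4)/2 = 10 over equal sample counts
        assert mpg(v, (0.0, 0.99)) == pytest.approx(10.0, rel=1e-6)

    def test_empty_window_raises(self):
        v = _wave(np.full(64, 1.0), UNIT_VELOCITY)
        with pytest.raises(ValueError):
            mpg(v, (0.5, 0.4))


class TestVTI:
    def test_constant_velocity(self):
        v = _wave(np.full(64, 1.0), UNIT_VELOCITY)
        assert vti(v, (0.2, 0.5)) == pytest.approx(30.0, rel=1e-9)

    def test_half_sine_closed_form(self):
        n = 20000
        t = np.linspace(0, 1, n, endpoint=False)
        v = _wave(2.2 * np.sin(np.pi * np.clip(t, 0, 0.3) / 0.3) * (t <= 0.3), UNIT_VELOCITY)
        assert vti(v, (0.0, 0.3)) == pytest.approx(2 * 2.2 * 0.3 / np.pi * 100, rel=1e-4)

    def test_zero_velocity(self):
        v = _wave(np.zeros(64), UNIT_VELOCITY)
        assert vti(v, (0.0, 0.5)) == 0.0


def _uniform_volume(speed=0.5, half=20.0, n=32):
    x = np.linspace(-half, half, n)
    z = np.linspace(0, 10, 4)
    frame = np.zeros((n, n, 4, 3))
    frame[..., 2] = speed
    return VelocityVolume((x, x, z), frame[None], np.array([0.0]))


class TestPlaneAnalysis:
    def test_uniform_flow_through_disc(self):
        vol = _uniform_volume(speed=0.5)
        plane = PlaneSection(np.array([0, 0, 5.0]), np.array([0, 0, 1.0]), 12.5)
        expected = 0.5 * np.pi * 12.5**2  # (m/s)*mm^2 == mL/s
        assert expected == pytest.approx(245.4, abs=0.1)
        assert plane_flow_rate(vol, plane) == pytest.approx(expected, rel=5e-3)

    def test_poiseuille_flow_rate_recovered(self, gen_spec):
        vol = gen_velocity_volume(gen_spec, duct_radius=12.5, Q=300.0)
        plane = PlaneSection(np.array([0, 0, 25.0]), np.array([0, 0, 1.0]), 12.5)
        assert plane_flow_rate(vol, plane) == pytest.approx(300.0, rel=5e-3)

    def test_reversed_normal_negates(self, gen_spec):
        vol = gen_velocity_volume(gen_spec, duct_radius=10.0, Q=200.0)
        up = PlaneSection(np.array([0, 0, 20.0]), np.array([0, 0, 1.0]), 10.0)
        dn = PlaneSection(np.array([0, 0, 20.0]), np.array([0, 0, -1.0]), 10.0)
        assert plane_flow_rate(vol, dn) == pytest.approx(-plane_flow_rate(vol, up), rel=1e-12)

    def test_uniform_field_mean_equals_max(self):
        vol = _uniform_volume(speed=0.7)
        plane = PlaneSection(np.array([0, 0, 5.0]), np.array([0, 0, 1.0]), 10.0)
        mean, mx = plane_velocity_stats(vol, plane)
        assert mean == pytest.approx(mx, rel=1e-12)
        assert mx == pytest.approx(0.7, rel=1e-12)

    def test_poiseuille_max_twice_mean(self, gen_spec):
        vol = gen_velocity_volume(gen_spec, duct_radius=12.5, Q=300.0)
        plane = PlaneSection(np.array([0, 0, 25.0]), np.array([0, 0, 1.0]), 12.5)
        mean, mx = plane_velocity_stats(vol, plane)
        assert mx / mean == pytest.approx(2.0, rel=1e-2)

    def test_zero_field(self):
        vol = _uniform_volume(speed=0.0)
        plane = PlaneSection(np.array([0, 0, 5.0]), np.array([0, 0, 1.0]), 10.0)
        assert plane_velocity_stats(vol, plane) == (0.0, 0.0)

    def test_flow_rate_error_decreases_with_resolution(self, gen_spec):
        vol = gen_velocity_volume(gen_spec, duct_radius=12.5, Q=300.0)
        plane = PlaneSection(np.array([0, 0, 25.0]), np.array([0, 0, 1.0]), 12.5)
        errs = [abs(plane_flow_rate(vol, plane, resolution=(r, r)) - 300.0)
                for r in (8, 32, 128)]
        assert errs[2] < errs[0]

    def test_plane_outside_grid_rejected(self):
        vol = _uniform_volume(half=10.0)
        plane = PlaneSection(np.array([0, 0, 5.0]), np.array([0, 0, 1.0]), 25.0)
        with pytest.raises(ValueError):
            plane_flow_rate(vol, plane)

    def test_frame_index_validated(self):
        vol = _uniform_volume()
        plane = PlaneSection(np.array([0, 0, 5.0]), np.array([0, 0, 1.0]), 5.0)
        with pytest.raises(IndexError):
            plane_flow_rate(vol, plane, frame=3)
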