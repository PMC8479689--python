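"""Trap-force model: closed forms vs the quadrature oracle and limits."""
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rbctweezer import (CellOpticalGeometry, OpticalConfig, beam_intensity,
                        force_offset_profile, trap_force_exact,
                        trap_force_numeric, trap_force_small_offset)
from rbctweezer.errors import InvalidArgumentError
from rbctweezer.trapforce import small_offset_parameter


def geom(radius, offset=0.0):
    return CellOpticalGeometry(radius=radius, trap_offset=offset,
                               thickness=min(1e-6, radius / 2))


class TestBeamIntensity:
    def test_on_axis_point_sees_peak(self, optics):
        g = CellOpticalGeometry(radius=1e-9, thickness=1e-10, trap_offset=0.0)
        peak = 2 * optics.power / (math.pi * optics.beam_waist ** 2)
        assert beam_intensity(optics, g, 0.3) == pytest.approx(peak, rel=1e-5)

    def test_centered_cell_at_one_waist_sees_exp_minus_two(self, optics):
        g = geom(optics.beam_waist)
        peak = 2 * optics.power / (math.pi * optics.beam_waist ** 2)
        for phi in (0.0, 1.0, math.pi, 5.0):
            assert beam_intensity(optics, g, phi) == pytest.approx(
                peak * math.exp(-2), rel=1e-12)

    def test_offset_cell_brightest_on_trap_side(self):
        cfg = OpticalConfig(power=30e-3, beam_waist=1e-6)
        g = geom(4e-6, offset=1e-6)
        assert beam_intensity(cfg, g, math.pi) > beam_intensity(cfg, g, 0.0)

    def test_rejects_non_finite_angle(self, optics):
        with pytest.raises(InvalidArgumentError):
            beam_intensity(optics, geom(2e-6), math.nan)


class TestClosedForms:
    def test_small_offset_matches_hand_evaluation(self):
        # independent re-evaluation of the closed form at 12 digits
        cfg = OpticalConfig(power=30e-3, beam_waist=3e-6, n_medium=1.334,
                            index_ratio=1.05)
        g = geom(2e-6, offset=0.5e-6)
        m2 = 1.05 ** 2
        expected = (16 * 1.334 * 30e-3 * (2e-6) ** 2
                    / (2.99792458e8 * (3e-6) ** 2)
                    * (m2 - 1) / (m2 + 1)
                    * math.exp(-2 / (3e-6) ** 2 * ((2e-6) ** 2 + (0.5e-6) ** 2)))
        res = trap_force_small_offset(cfg, g)
        assert res.magnitude == pytest.approx(expected, rel=1e-12)
        assert res.direction_sign == -1
        assert res.small_offset_parameter == pytest.approx(
            4 * 0.5e-6 * 2e-6 / (3e-6) ** 2, rel=1e-12)

    def test_index_matched_cell_feels_no_force(self, geometry):
        cfg = OpticalConfig(index_ratio=1.0)
        assert trap_force_small_offset(cfg, geometry).magnitude == 0.0
        assert trap_force_exact(cfg, geometry).magnitude == 0.0
        assert trap_force_numeric(cfg, geometry).magnitude == 0.0

    def test_exact_reduces_to_small_offset_at_zero_offset(self, optics):
        g = geom(2e-6, offset=0.0)
        assert (trap_force_exact(optics, g).magnitude
                == trap_force_small_offset(optics, g).magnitude)

    def test_force_decays_exponentially_at_large_offset(self, optics):
        far = geom(2e-6, offset=10 * optics.beam_waist)
        near = geom(2e-6, offset=0.0)
        assert (trap_force_small_offset(optics, far).magnitude
                < 1e-10 * trap_force_small_offset(optics, near).magnitude)

    def test_small_offset_error_below_0p1pct_at_argument_0p05(self, optics):
        rho = 2e-6
        offset = 0.05 * optics.beam_waist ** 2 / (4 * rho)
        g = geom(rho, offset)
        exact = trap_force_exact(optics, g).magnitude
        approx = trap_force_small_offset(optics, g).magnitude
        assert abs(exact - approx) / exact < 1e-3

    def test_small_offset_deviation_grows_with_argument(self, optics):
        rho = 2e-6
        devs = []
        for arg in (0.05, 0.2, 0.5, 1.0, 2.0):
            g = geom(rho, arg * optics.beam_waist ** 2 / (4 * rho))
            e = trap_force_exact(optics, g).magnitude
            s = trap_force_small_offset(optics, g).magnitude
            devs.append(abs(e - s) / e)
        assert devs == sorted(devs)

    def test_regime_violation_logged(self, optics, caplog):
        rho = 2e-6
        g = geom(rho, 0.5 * optics.beam_waist ** 2 / (4 * rho))
        with caplog.at_level("WARNING", logger="rbctweezer.trapforce"):
            trap_force_small_offset(optics, g)
        assert any("small-offset" in r.message for r in caplog.records)


class TestQuadratureOracle:
    def test_closed_form_matches_quadrature_over_random_draws(self):
        rng = np.random.default_rng(42)
        for _ in range(100):
            wo = rng.uniform(1e-6, 4e-6)
            rho = rng.uniform(1e-6, 6e-6)
            offset = rng.uniform(0.0, 2.0 * wo ** 2 / (4 * rho))
            cfg = OpticalConfig(power=rng.uniform(5e-3, 50e-3), beam_waist=wo,
                                index_ratio=rng.uniform(1.01, 1.2))
            g = geom(rho, offset)
            assert small_offset_parameter(cfg, g) <= 2.0 + 1e-9
            exact = trap_force_exact(cfg, g).magnitude
            numeric = trap_force_numeric(cfg, g).magnitude
            assert abs(exact - numeric) / numeric < 0.01

    def test_quadrature_converged_in_phi(self, optics):
        g = geom(3e-6, offset=0.4e-6)
        coarse = trap_force_numeric(optics, g, n_phi=256).magnitude
        fine = trap_force_numeric(optics, g, n_phi=512).magnitude
        assert abs(fine - coarse) / fine < 1e-6

    def test_monte_carlo_surface_sampling_cross_check(self, optics):
        # independent oracle: Monte-Carlo average of the intensity kernel
        # over the cylinder wall instead of deterministic quadrature
        rng = np.random.default_rng(7)
        g = geom(2e-6, offset=0.6e-6)
        phi = rng.uniform(0, 2 * math.pi, 200_000)
        w2 = optics.beam_waist ** 2
        kernel = np.exp(-2 * ((g.trap_offset + g.radius * np.cos(phi)) ** 2
                              + (g.radius * np.sin(phi)) ** 2) / w2)
        m2 = optics.index_ratio ** 2
        prefactor = (16 * optics.n_medium * optics.power * g.radius ** 2
                     / (optics.light_speed * w2) * abs(m2 - 1) / (m2 + 1))
        mc = prefactor * kernel.mean()
        numeric = trap_force_numeric(optics, g).magnitude
        assert numeric == pytest.approx(mc, rel=0.01)

    def test_resolution_preconditions(self, optics, geometry):
        with pytest.raises(InvalidArgumentError):
            trap_force_numeric(optics, geometry, n_phi=8)
        with pytest.raises(InvalidArgumentError):
            trap_force_numeric(optics, geometry, n_y=1)


class TestScaling:
    @given(scale=st.floats(min_value=0.1, max_value=10.0))
    @settings(max_examples=25, deadline=None)
    def test_linear_in_power_and_medium_index(self, scale):
        g = geom(2e-6, offset=0.3e-6)
        base = trap_force_exact(OpticalConfig(), g).magnitude
        scaled_p = trap_force_exact(OpticalConfig(power=30e-3 * scale), g).magnitude
        assert scaled_p == pytest.approx(base * scale, rel=1e-9)
        n1 = 1.334 * min(scale, 1.2)
        scaled_n = trap_force_exact(OpticalConfig(n_medium=max(n1, 1.0)), g).magnitude
        assert scaled_n == pytest.approx(base * max(n1, 1.0) / 1.334, rel=1e-9)

    def test_radius_scaling_at_zero_offset(self, optics):
        # magnitude ~ rho^2 exp(-2 rho^2 / w0^2) at rt = 0
        r1, r2 = 1.5e-6, 2.5e-6
        f1 = trap_force_exact(optics, geom(r1)).magnitude
        f2 = trap_force_exact(optics, geom(r2)).magnitude
        w2 = optics.beam_waist ** 2
        expected_ratio = (r2 / r1) ** 2 * math.exp(-2 * (r2 ** 2 - r1 ** 2) / w2)
        assert f2 / f1 == pytest.approx(expected_ratio, rel=1e-9)


class TestOffsetProfile:
    def test_profile_matches_pointwise_evaluation(self, optics):
        offsets = [0.0, 0.2e-6, 0.5e-6, 1.0e-6]
        profile = force_offset_profile(optics, geom(2e-6), offsets)
        assert [p.magnitude for p in profile] == [
            trap_force_exact(optics, geom(2e-6, o)).magnitude for o in offsets]

    def test_small_argument_profile_is_non_increasing(self, optics):
        rho = 1e-6
        offsets = np.linspace(0, 0.02 * optics.beam_waist ** 2 / (4 * rho), 8)
        mags = [p.magnitude for p in force_offset_profile(optics, geom(rho), offsets)]
        assert all(a >= b for a, b in zip(mags, mags[1:]))

    def test_empty_profile(self, optics, geometry):
        assert force_offset_profile(optics, geometry, []) == []

    def test_negative_offset_rejected_with_index(self, optics, geometry):
        with pytest.raises(InvalidArgumentError, match=r"offsets\[1\]"):
            force_offset_profile(optics, geometry, [0.0, -1e-6])
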