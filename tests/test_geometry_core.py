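"""Superellipse rings, NACA section polynomial, thickness envelopes."""
import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from bracketvol.exceptions import InvalidExponent, OutOfChord
from bracketvol.geometry_core import (
    cephalofoil_envelope,
    naca_half_thickness,
    superellipse_area,
    superellipse_vertices,
    thickness_envelope,
)


def _shoelace(verts):
    x, y = verts[:-1, 0], verts[:-1, 1]  # drop duplicate endpoint
    return 0.5 * abs(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))


class TestSuperellipse:
    def test_n2_theta0_is_ellipse_vertex(self):
        sec = superellipse_vertices(10, 5, 2, center=(3, 4))
        assert np.allclose(sec.vertices[0], [13, 4, 0])

    def test_default_181_vertices_with_duplicate_endpoint(self):
        sec = superellipse_vertices(10, 5, 2.4)
        assert len(sec.vertices) == 181
        assert np.array_equal(sec.vertices[0], sec.vertices[-1])
        # one vertex per 2 degrees of angular parameter
        theta1 = np.arctan2(np.sign(sec.vertices[1, 1]),
                            np.sign(sec.vertices[1, 0]))
        assert theta1 != 0  # moved off the start

    def test_ring_area_matches_gamma_closed_form(self):
        # oracle: shoelace polygon area vs 4ab G(1+1/n)^2 / G(1+2/n)
        sec = superellipse_vertices(100, 50, 2.5, m=721)
        closed = superellipse_area(100, 50, 2.5)
        assert abs(_shoelace(sec.vertices) - closed) / closed < 0.0005

    @given(st.floats(min_value=0.5, max_value=6.0),
           st.floats(min_value=0.5, max_value=6.0))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_vertices_satisfy_superellipse_equation(self, n, ratio):
        a, b = 10.0, 10.0 * ratio
        sec = superellipse_vertices(a, b, n, m=91)
        lhs = (np.abs(sec.vertices[:, 0] / a) ** n
               + np.abs(sec.vertices[:, 1] / b) ** n)
        assert np.allclose(lhs, 1.0, rtol=1e-9, atol=1e-9)

    def test_area_strictly_increasing_in_n(self):
        ns = [1.5, 2.0, 2.5, 3.0, 4.0]
        areas = [superellipse_area(100, 50, n) for n in ns]
        assert np.all(np.diff(areas) > 0)

    def test_invalid_exponent(self):
        with pytest.raises(InvalidExponent):
            superellipse_vertices(1, 1, 0)
        with pytest.raises(InvalidExponent):
            superellipse_area(1, 1, -2)


class TestNaca:
    def test_leading_edge_zero(self):
        assert naca_half_thickness(0.0, 20) == 0.0

    def test_printed_polynomial_values(self):
        # direct evaluation of the section polynomial
        assert naca_half_thickness(0.3, 20) == pytest.approx(0.10003, abs=2e-5)
        # open trailing edge of the printed coefficients
        assert naca_half_thickness(1.0, 20) == pytest.approx(0.0021, abs=1e-4)

    def test_linear_in_thickness(self):
        x = np.linspace(0, 1, 11)
        assert np.allclose(naca_half_thickness(x, 30),
                           3.0 * naca_half_thickness(x, 10))

    def test_max_thickness_near_30pct_chord(self):
        x = np.linspace(0, 1, 10001)
        y = naca_half_thickness(x, 20)
        assert 2 * y.max() == pytest.approx(0.20, rel=0.01)
        assert x[np.argmax(y)] == pytest.approx(0.30, abs=0.01)

    def test_out_of_chord(self):
        with pytest.raises(OutOfChord):
            naca_half_thickness(1.2, 20)


class TestEnvelope:
    def test_factor_one_at_thickest_point(self):
        assert thickness_envelope([0.3], 0.3)[0] == pytest.approx(1.0)
        assert thickness_envelope([0.0], 0.0)[0] == pytest.approx(1.0)

    def test_midpoint_factor_is_sqrt_half(self):
        # halfway between thickest point and tip, thickness scales by 0.5^0.5
        assert thickness_envelope([0.5], 0.0)[0] == pytest.approx(
            np.sqrt(0.5), abs=1e-12)
        assert thickness_envelope([0.75], 0.5)[0] == pytest.approx(
            np.sqrt(0.5), abs=1e-12)

    def test_zero_at_tips(self):
        assert thickness_envelope([1.0], 0.0)[0] == 0.0
        env = thickness_envelope([0.0, 1.0], 0.5)
        assert np.allclose(env, 0.0)

    @given(st.floats(min_value=0.0, max_value=1.0))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_monotone_nonincreasing_away_from_peak(self, tf):
        s = np.linspace(0, 1, 201)
        env = thickness_envelope(s, tf)
        left = env[s <= tf]
        right = env[s >= tf]
        assert np.all(np.diff(left) >= -1e-12)
        assert np.all(np.diff(right) <= 1e-12)
        assert env.max() <= 1.0 + 1e-12

    def test_out_of_range_clamped_with_warning(self):
        with pytest.warns(UserWarning):
            env = thickness_envelope([-0.2, 1.3], 0.5)
        assert np.all((env >= 0) & (env <= 1))

    def test_cephalofoil_thick_at_both_ends(self):
        env = cephalofoil_envelope([0.0, 0.5, 1.0], mid_factor=0.6)
        assert env[0] == pytest.approx(1.0)
        assert env[2] == pytest.approx(1.0)
        assert env[1] == pytest.approx(0.6)
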