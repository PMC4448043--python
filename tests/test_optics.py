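"""Optical primitives: closed-form examples, distributional and exact properties."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from optomc import (
    OpticalMedium,
    attenuate,
    critical_angle,
    fresnel_unpolarized,
    refract,
    rotate_direction,
    sample_free_path,
    sample_hg_cos,
)
from optomc.rng import stream_floats

TISSUE = OpticalMedium("tissue", 1.36, mu_a=0.07, mu_s=11.7, g=0.88)


class TestFreePath:
    @pytest.mark.parametrize(
        "mu_t, u, expected",
        [
            (11.77, 1.0, 0.0),  # -ln(1) = 0
            (11.77, math.exp(-1.0), 1.0 / 11.77),  # one mean free path
            (0.0, 0.5, math.inf),  # transparent medium: no interaction
        ],
    )
    def test_closed_form(self, mu_t, u, expected):
        assert sample_free_path(mu_t, u) == pytest.approx(expected, rel=1e-12)

    @pytest.mark.parametrize("u", [0.0, 1.0 + 1e-12, -0.1])
    def test_invalid_deviate(self, u):
        with pytest.raises(ValueError):
            sample_free_path(11.77, u)

    def test_mean_equals_inverse_mu_t(self):
        u = 1.0 - stream_floats(99, 0, 1_000_000)
        s = -np.log(u) / 11.77
        se = s.std(ddof=1) / math.sqrt(len(s))
        assert abs(s.mean() - 1.0 / 11.77) < 3.0 * se

    def test_exponential_distribution_ks(self):
        """Draws reproduce Beer-Lambert exponential free paths (1% KS level)."""
        mu_t = 11.77
        u = 1.0 - stream_floats(7, 3, 100_000)
        s = -np.log(u) / mu_t
        stat = stats.kstest(s, "expon", args=(0.0, 1.0 / mu_t)).statistic
        assert stat < 1.63 / math.sqrt(len(s))  # 1% critical value


class TestAttenuate:
    @pytest.mark.parametrize(
        "mu_a, mu_s, expected_w, expected_abs",
        [
            (0.0, 5.0, 1.0, 0.0),  # pure scatterer
            (5.0, 0.0, 0.0, 1.0),  # pure absorber
            (0.07, 11.7, 11.7 / 11.77, 0.07 / 11.77),  # cortical tissue
        ],
    )
    def test_split(self, mu_a, mu_s, expected_w, expected_abs):
        med = OpticalMedium("m", 1.36, mu_a=mu_a, mu_s=mu_s, g=0.0)
        w, absorbed = attenuate(1.0, med)
        assert w == pytest.approx(expected_w, abs=1e-12)
        assert absorbed == pytest.approx(expected_abs, abs=1e-12)

    def test_transparent_medium_rejected(self):
        with pytest.raises(ValueError):
            attenuate(1.0, OpticalMedium("void", 1.0))

    @given(w=st.floats(1e-12, 1.0), mu_a=st.floats(0.0, 50.0), mu_s=st.floats(1e-6, 50.0))
    @settings(max_examples=300, derandomize=True)
    def test_weight_conservation_per_call(self, w, mu_a, mu_s):
        """absorbed + surviving reproduces the input weight to 1 ulp, and the
        surviving weight never exceeds the input."""
        med = OpticalMedium("m", 1.4, mu_a=mu_a, mu_s=mu_s)
        new_w, absorbed = attenuate(w, med)
        assert new_w + absorbed == pytest.approx(w, rel=4e-16)
        assert 0.0 <= new_w <= w


class TestHenyeyGreenstein:
    @pytest.mark.parametrize(
        "g, u, expected",
        [
            (0.0, 0.5, 0.0),
            (0.88, 0.0, -1.0),
            (0.88, 1.0, 1.0),
            (0.88, 0.5, 0.979264),  # frozen from the closed form
        ],
    )
    def test_inverse_cdf(self, g, u, expected):
        assert sample_hg_cos(g, u) == pytest.approx(expected, abs=1e-12)

    def test_invalid_anisotropy(self):
        with pytest.raises(ValueError):
            sample_hg_cos(1.0, 0.5)

    def test_first_moment_is_g(self):
        g = 0.88
        u = stream_floats(5, 0, 1_000_000)
        tmp = (1.0 - g * g) / (1.0 - g + 2.0 * g * u)
        cos_t = (1.0 + g * g - tmp * tmp) / (2.0 * g)
        se = cos_t.std(ddof=1) / math.sqrt(len(cos_t))
        assert abs(cos_t.mean() - g) < 3.0 * se

    def test_isotropic_limit_uniform_ks(self):
        u = stream_floats(6, 1, 100_000)
        cos_t = 2.0 * u - 1.0
        stat = stats.kstest(cos_t, "uniform", args=(-1.0, 2.0)).statistic
        assert stat < 1.63 / math.sqrt(len(cos_t))

    @given(g=st.floats(-0.99, 0.99), u=st.floats(0.0, 1.0))
    @settings(max_examples=300, derandomize=True)
    def test_result_in_range(self, g, u):
        assert -1.0 <= sample_hg_cos(g, u) <= 1.0


class TestRotateDirection:
    def test_no_deflection_keeps_axis(self):
        assert rotate_direction((0.0, 0.0, 1.0), 1.0, 2.1) == pytest.approx((0.0, 0.0, 1.0))

    def test_orthogonal_deflection_convention(self):
        # 90 degrees at zero azimuth tips +z toward +x
        d = rotate_direction((0.0, 0.0, 1.0), 0.0, 0.0)
        assert d == pytest.approx((1.0, 0.0, 0.0), abs=1e-12)

    @given(
        v=st.tuples(*[st.floats(-1, 1)] * 3).filter(lambda v: 1e-3 < sum(x * x for x in v)),
        cos_t=st.floats(-1.0, 1.0),
        phi=st.floats(0.0, 2.0 * math.pi, exclude_max=True),
    )
    @settings(max_examples=500, derandomize=True)
    def test_unit_norm_and_deflection_cosine(self, v, cos_t, phi):
        """Rotation preserves unit length and realises the requested cosine."""
        norm = math.sqrt(sum(x * x for x in v))
        d = tuple(x / norm for x in v)
        out = rotate_direction(d, cos_t, phi)
        assert sum(x * x for x in out) == pytest.approx(1.0, abs=1e-12)
        dot = sum(a * b for a, b in zip(d, out))
        assert dot == pytest.approx(cos_t, abs=1e-9)

    def test_near_pole_stability(self):
        d = (1e-10, 0.0, math.sqrt(1.0 - 1e-20))
        out = rotate_direction(d, 0.3, 1.0)
        assert sum(x * x for x in out) == pytest.approx(1.0, abs=1e-12)
        assert sum(a * b for a, b in zip(d, out)) == pytest.approx(0.3, abs=1e-9)


class TestFresnel:
    def test_index_matched_is_transparent(self):
        assert fresnel_unpolarized(1.36, 1.36, 0.3) == 0.0

    def test_normal_incidence_sapphire_tissue(self):
        expected = ((1.77 - 1.36) / (1.77 + 1.36)) ** 2
        assert fresnel_unpolarized(1.77, 1.36, 1.0) == pytest.approx(expected, abs=1e-12)

    def test_total_internal_reflection(self):
        crit = critical_angle(1.77, 1.36)
        assert math.degrees(crit) == pytest.approx(50.2, abs=0.05)
        assert fresnel_unpolarized(1.77, 1.36, math.cos(math.radians(55.0))) == 1.0

    def test_continuous_at_critical_angle(self):
        crit = critical_angle(1.77, 1.36)
        just_below = fresnel_unpolarized(1.77, 1.36, math.cos(crit - 1e-6))
        assert just_below > 0.95

    @given(n1=st.floats(1.0, 2.5), n2=st.floats(1.0, 2.5), cos_i=st.floats(1e-6, 1.0))
    @settings(max_examples=300, derandomize=True)
    def test_reflectance_is_probability(self, n1, n2, cos_i):
        r = fresnel_unpolarized(n1, n2, cos_i)
        assert 0.0 <= r <= 1.0

    def test_invalid_geometry(self):
        with pytest.raises(ValueError):
            fresnel_unpolarized(1.5, 1.3, 0.0)


class TestRefract:
    def test_normal_incidence_unchanged(self):
        d = refract((0.0, 0.0, 1.0), (0.0, 0.0, -1.0), 1.77, 1.36)
        assert d == pytest.approx((0.0, 0.0, 1.0), abs=1e-12)

    def test_snell_30_degrees(self):
        ti = math.radians(30.0)
        d = refract((math.sin(ti), 0.0, math.cos(ti)), (0.0, 0.0, -1.0), 1.77, 1.36)
        theta_t = math.asin(d[0])
        assert theta_t == pytest.approx(math.asin(1.77 * 0.5 / 1.36), abs=1e-9)

    def test_tir_flag(self):
        ti = math.radians(60.0)  # beyond the 50.2 degree critical angle
        assert refract((math.sin(ti), 0.0, math.cos(ti)), (0.0, 0.0, -1.0), 1.77, 1.36) is None

    @given(
        theta=st.floats(0.01, 0.6),
        phi=st.floats(0.0, 2.0 * math.pi, exclude_max=True),
        n1=st.floats(1.0, 2.0),
        n2=st.floats(1.0, 2.0),
    )
    @settings(max_examples=300, derandomize=True)
    def test_snell_invariant_and_plane_of_incidence(self, theta, phi, n1, n2):
        d = (math.sin(theta) * math.cos(phi), math.sin(theta) * math.sin(phi), math.cos(theta))
        out = refract(d, (0.0, 0.0, -1.0), n1, n2)
        sin_i = math.sin(theta)
        if n1 * sin_i / n2 > 1.0:
            assert out is None
            return
        sin_t = math.sqrt(out[0] ** 2 + out[1] ** 2)
        assert n1 * sin_i == pytest.approx(n2 * sin_t, abs=1e-9)
        # transmitted ray stays in the plane of incidence
        cross = d[0] * out[1] - d[1] * out[0]
        assert cross == pytest.approx(0.0, abs=1e-9)


class TestOpticalMedium:
    def test_albedo_and_mu_t(self):
        assert TISSUE.mu_t == pytest.approx(11.77)
        assert TISSUE.albedo == pytest.approx(11.7 / 11.77)

    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(refractive_index=0.9),
            dict(refractive_index=1.4, mu_a=-0.1),
            dict(refractive_index=1.4, g=1.0),
        ],
    )
    def test_invalid_parameters_rejected(self, kwargs):
        with pytest.raises(ValueError):
            OpticalMedium("bad", **kwargs)
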