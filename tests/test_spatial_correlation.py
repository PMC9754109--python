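import numpy as np
import pytest

from dfcc.optical_flow import FlowField
from dfcc.spatial_correlation import (
    AngleField,
    Correlation2D,
    ZeroVarianceError,
    angles_from_flow,
    circular_autocorrelation,
    correlation_by_time_lag,
    magnitude_autocorrelation,
    radial_project,
)
from oracles import direction_correlation_double_loop, magnitude_correlation_double_loop


def wrap_angle(a):
    out = np.mod(a, 2 * np.pi)
    return np.where(out > np.pi, out - 2 * np.pi, out)


class TestAngles:
    # all seven branches of the piecewise arctangent definition
    @pytest.mark.parametrize(
        "u,v,expected",
        [
            (1.0, 1.0, np.pi / 4),          # u >= 0: plain arctan
            (0.0, 1.0, np.pi / 2),          # u = 0, v > 0
            (-1.0, 1.0, 3 * np.pi / 4),     # u < 0, v >= 0: +pi
            (-1.0, -1.0, -3 * np.pi / 4),   # u < 0, v < 0: -pi
            (1.0, 0.0, 0.0),                # positive x-axis
            (-1.0, 0.0, np.pi),             # negative x-axis
            (0.0, -1.0, -np.pi / 2),        # u = 0, v < 0
        ],
    )
    def test_case_table(self, u, v, expected):
        field = angles_from_flow(FlowField(np.array([[u]]), np.array([[v]])))
        assert field.gamma[0, 0] == pytest.approx(expected, abs=1e-12)

    def test_zero_vector_undefined(self):
        field = angles_from_flow(FlowField(np.zeros((2, 2)), np.zeros((2, 2))))
        assert not field.defined.any()

    def test_defined_range(self, rng):
        u, v = rng.normal(size=(2, 16, 16))
        g = angles_from_flow(FlowField(u, v)).gamma
        assert np.all(g > -np.pi) and np.all(g <= np.pi)


class TestCircularCorrelation:
    def test_constant_angle_field_is_unity(self):
        corr = circular_autocorrelation(AngleField(np.full((8, 8), 1.234)))
        assert np.nanmax(np.abs(corr.r - 1.0)) < 1e-12

    @pytest.mark.parametrize("eps", [0.01, 0.1])
    def test_wraparound_difference_is_2eps(self, eps):
        """Vectors at pi-eps and -pi+eps point nearly the same way: their
        correlation must be cos(2*eps), not cos(2*pi - 2*eps)."""
        field = AngleField(np.array([[np.pi - eps, -np.pi + eps]]))
        corr = circular_autocorrelation(field)
        lag = corr.r[corr.origin[0], corr.origin[1] + 1]
        assert lag == pytest.approx(np.cos(2 * eps), abs=1e-12)
        # the raw linear angle difference is 2*pi - 2*eps, i.e. huge; the
        # circular embedding must still see nearly identical directions
        assert lag > 0.9

    @pytest.mark.parametrize("shape", [(5, 7), (8, 8), (12, 12)])
    @pytest.mark.parametrize("seed", [0, 1])
    def test_matches_double_loop_oracle(self, shape, seed):
        g = np.random.default_rng(seed).uniform(-np.pi, np.pi, shape)
        corr = circular_autocorrelation(AngleField(g))
        ref, counts = direction_correlation_double_loop(g)
        np.testing.assert_allclose(corr.r, ref, atol=1e-10)
        np.testing.assert_array_equal(corr.counts, counts)

    def test_oracle_agreement_with_undefined_entries(self):
        g = np.random.default_rng(7).uniform(-np.pi, np.pi, (9, 9))
        g[np.random.default_rng(8).random((9, 9)) < 0.2] = np.nan
        corr = circular_autocorrelation(AngleField(g))
        ref, counts = direction_correlation_double_loop(g)
        np.testing.assert_allclose(
            np.nan_to_num(corr.r), np.nan_to_num(ref), atol=1e-10
        )
        np.testing.assert_array_equal(corr.counts, counts)

    def test_rotation_offset_invariance(self, rng):
        """Angle differences are preserved under a global rotation."""
        g = rng.uniform(-np.pi, np.pi, (10, 10))
        r1 = circular_autocorrelation(AngleField(g)).r
        r2 = circular_autocorrelation(AngleField(wrap_angle(g + 0.9))).r
        np.testing.assert_allclose(r1, r2, atol=1e-10)

    def test_symmetry_exact(self, rng):
        g = rng.uniform(-np.pi, np.pi, (9, 11))
        r = circular_autocorrelation(AngleField(g)).r
        np.testing.assert_array_equal(r, r[::-1, ::-1])

    def test_origin_exactly_one_and_bounded(self, rng):
        g = rng.uniform(-np.pi, np.pi, (12, 12))
        corr = circular_autocorrelation(AngleField(g))
        assert corr.r[corr.origin] == 1.0
        assert np.nanmax(np.abs(corr.r)) <= 1 + 1e-9

    def test_all_undefined_rejected(self):
        with pytest.raises(ValueError):
            circular_autocorrelation(AngleField(np.full((4, 4), np.nan)))

    def test_iid_uniform_field_decorrelated(self):
        """For i.i.d. uniform directions the off-origin correlation is
        sampling noise of order 1/sqrt(pair count)."""
        g = np.random.default_rng(3).uniform(-np.pi, np.pi, (64, 64))
        curve = radial_project(circular_autocorrelation(AngleField(g)), 1.0)
        off = curve.rho_px > 0
        assert np.all(np.abs(curve.r[off]) < 3 / np.sqrt(curve.counts[off]))


class TestMagnitudeCorrelation:
    @pytest.mark.parametrize("shape", [(5, 7), (8, 8), (12, 12)])
    def test_matches_double_loop_oracle(self, shape):
        g = np.random.default_rng(11)
        ff = FlowField(g.normal(0.5, 0.1, shape), g.normal(0.0, 0.1, shape))
        corr = magnitude_autocorrelation(ff)
        ref = magnitude_correlation_double_loop(ff.magnitude)
        np.testing.assert_allclose(corr.r, ref, atol=1e-10)

    def test_zero_variance_rejected(self):
        ff = FlowField(np.full((8, 8), 0.5), np.zeros((8, 8)))
        with pytest.raises(ZeroVarianceError):
            magnitude_autocorrelation(ff)

    def test_sinusoid_autocorrelation_is_cosine(self):
        """A pure sinusoid along x has cosine autocorrelation in x-lag."""
        period = 16
        x = np.arange(64)
        m = 0.5 + 0.1 * np.sin(2 * np.pi * x / period)
        ff = FlowField(np.tile(m, (64, 1)), np.zeros((64, 64)))
        corr = magnitude_autocorrelation(ff)
        oy, ox = corr.origin
        for dx in (0, 4, 8, 12):
            expected = np.cos(2 * np.pi * dx / period)
            assert corr.r[oy, ox + dx] == pytest.approx(expected, abs=0.1)


class TestRadialProjection:
    def test_three_four_five_lag_bin(self, rng):
        g = rng.uniform(-np.pi, np.pi, (12, 12))
        corr = circular_autocorrelation(AngleField(g))
        curve = radial_project(corr, bin_width=1.0, max_lag=8)
        assert 5.0 in curve.rho_px  # the (3,4) lag lands in the rho=5 bin
        ly, lx = np.meshgrid(corr.lags_y, corr.lags_x, indexing="ij")
        in_bin = np.abs(np.hypot(lx, ly) - 5.0) <= 0.5
        assert in_bin[corr.origin[0] + 3, corr.origin[1] + 4]

    def test_zero_bin_exactly_one(self, rng):
        g = rng.uniform(-np.pi, np.pi, (10, 10))
        curve = radial_project(circular_autocorrelation(AngleField(g)), 1.0)
        assert curve.rho_px[0] == 0.0
        assert curve.r[0] == 1.0
        assert np.all(np.diff(curve.rho_px) > 0)

    def test_isotropic_exponential_reconstructed(self):
        n = 41
        lags = np.arange(-(n - 1) // 2, (n + 1) // 2)
        ly, lx = np.meshgrid(lags, lags, indexing="ij")
        rho = np.hypot(lx, ly)
        corr = Correlation2D(
            r=np.exp(-rho / 5.0), counts=np.ones_like(rho, dtype=float),
            lags_y=lags, lags_x=lags,
        )
        curve = radial_project(corr, 1.0, max_lag=15)
        # exact oracle: unweighted mean of exp(-rho/5) over the lags that
        # fall in each bin
        for centre, got in zip(curve.rho_px, curve.r):
            in_bin = np.abs(rho - centre) <= 0.5
            assert got == pytest.approx(np.exp(-rho[in_bin] / 5.0).mean(), abs=1e-12)
        # and the curve still tracks the generating radial function
        np.testing.assert_allclose(curve.r, np.exp(-curve.rho_px / 5.0), atol=0.05)

    def test_bad_bin_width_rejected(self, rng):
        g = rng.uniform(-np.pi, np.pi, (8, 8))
        corr = circular_autocorrelation(AngleField(g))
        with pytest.raises(ValueError):
            radial_project(corr, bin_width=0.0)

    def test_nm_conversion(self, rng):
        g = rng.uniform(-np.pi, np.pi, (8, 8))
        curve = radial_project(circular_autocorrelation(AngleField(g)), 1.0)
        np.testing.assert_allclose(curve.rho_nm(65.0), curve.rho_px * 65.0)


class TestCorrelationByTimeLag:
    def _random_flow(self, seed, lag=1, t0=0):
        g = np.random.default_rng(seed)
        return FlowField(g.normal(0.3, 0.1, (16, 16)), g.normal(0, 0.1, (16, 16)),
                         frame_pair=(t0, t0 + lag))

    def test_single_pair_equals_direct_computation(self):
        ff = self._random_flow(0)
        out = correlation_by_time_lag([ff])
        direct = radial_project(circular_autocorrelation(angles_from_flow(ff)), 1.0)
        np.testing.assert_allclose(out[1][0].r, direct.r, atol=1e-12)

    def test_identical_fields_average_to_same_curve(self):
        ff = self._random_flow(1)
        ff2 = FlowField(ff.u.copy(), ff.v.copy(), frame_pair=(1, 2))
        single = correlation_by_time_lag([ff])[1][0]
        avg = correlation_by_time_lag([ff, ff2])[1][0]
        np.testing.assert_allclose(avg.r, single.r, atol=1e-12)
        assert avg.counts[0] == 2 * single.counts[0]

    def test_groups_by_frame_pair_lag(self):
        fields = [self._random_flow(s, lag=1, t0=s) for s in range(3)]
        fields += [self._random_flow(s + 10, lag=2, t0=s) for s in range(2)]
        out = correlation_by_time_lag(fields)
        assert sorted(out) == [1, 2]

    def test_empty_lag_set_rejected(self):
        with pytest.raises(ValueError):
            correlation_by_time_lag([self._random_flow(0)], lags=set())

    def test_missing_lag_rejected(self):
        with pytest.raises(ValueError):
            correlation_by_time_lag([self._random_flow(0)], lags={3})

    def test_zero_variance_magnitude_yields_none(self):
        ff = FlowField(np.full((16, 16), 0.5), np.zeros((16, 16)))
        out = correlation_by_time_lag([ff])
        dcurve, mcurve = out[1]
        assert mcurve is None
        assert dcurve.r[0] == 1.0
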