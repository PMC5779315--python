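"""Closed-form curves and the information-theoretic identities behind them."""

import math

import mpmath
import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from stmbound import (
    ChannelSpec,
    PowerAllocation,
    coded_storage_mse_bound,
    direct_storage_mse,
    gaussian_capacity,
    heuristic_identity_check,
    per_item_rate,
    pooled_diffusivity,
    rate_distortion_interval,
    resource,
    sum_rate_bound,
)
from stmbound.theory import coded_storage_mse_grid, deg2_to_norm, norm_to_deg2

positive = st.floats(min_value=1e-3, max_value=1e3)


class TestDirectStorage:
    @pytest.mark.parametrize(
        "kwargs, expected",
        [
            (dict(phi=1, n_items=3, n_channels=2, diffusivity=0.7, duration=0.0), 0.0),
            (dict(phi=1, n_items=2, n_channels=4, diffusivity=0.5, duration=1.0), 0.5),
        ],
    )
    def test_values(self, kwargs, expected):
        assert direct_storage_mse(ChannelSpec(**kwargs)) == pytest.approx(expected)

    @given(d=positive, k=st.floats(1, 20), n=positive, t=positive)
    def test_linearity_in_time(self, d, k, n, t):
        base = ChannelSpec(n_items=k, n_channels=n, diffusivity=d, duration=t)
        doubled = ChannelSpec(n_items=k, n_channels=n, diffusivity=d, duration=2 * t)
        assert direct_storage_mse(doubled) == pytest.approx(
            2 * direct_storage_mse(base), rel=1e-12
        )

    @given(d=positive, k=st.floats(1, 20), n=positive, t=positive, c=st.floats(1, 8))
    def test_invariance_under_joint_scaling(self, d, k, n, t, c):
        a = ChannelSpec(n_items=k, n_channels=n, diffusivity=d, duration=t)
        b = ChannelSpec(n_items=c * k, n_channels=c * n, diffusivity=d, duration=t)
        assert direct_storage_mse(a) == pytest.approx(direct_storage_mse(b), rel=1e-12)

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            ChannelSpec(n_channels=0.0)
        with pytest.raises(ValueError):
            ChannelSpec(diffusivity=-1.0)


class TestPooledDiffusivity:
    def test_identity_split_and_hand_value(self):
        assert pooled_diffusivity(0.37, 5, 5) == pytest.approx(0.37)
        assert pooled_diffusivity(1.0, 2, 4) == pytest.approx(0.5)

    @given(d=positive, k=st.floats(1, 20))
    def test_strictly_decreasing_in_channels(self, d, k):
        vals = [pooled_diffusivity(d, k, n) for n in (1.0, 2.0, 5.0, 50.0)]
        assert all(a > b for a, b in zip(vals, vals[1:]))

    def test_zero_channels_rejected(self):
        with pytest.raises(ValueError):
            pooled_diffusivity(1.0, 2, 0)


class TestRates:
    def test_capacity_values(self):
        assert gaussian_capacity(0.0) == 0.0
        assert gaussian_capacity(math.e**2 - 1) == pytest.approx(1.0, rel=1e-12)
        with pytest.raises(ValueError):
            gaussian_capacity(-0.1)

    @given(snr=st.floats(1e-6, 1e6))
    def test_capacity_increasing_concave(self, snr):
        lo, hi = gaussian_capacity(snr), gaussian_capacity(3 * snr)
        mid = gaussian_capacity(2 * snr)  # arithmetic midpoint of snr values
        assert lo < mid < hi
        assert mid > (lo + hi) / 2  # concavity in snr

    def test_sum_rate_special_cases(self):
        alloc = PowerAllocation.equal(4)
        assert sum_rate_bound(alloc, [], 0.5, 1.0) == 0.0
        zero = PowerAllocation([0.0] * 4)
        assert sum_rate_bound(zero, [0, 1, 2, 3], 0.5, 1.0) == 0.0
        # full set, unit power, 2DT = 1 -> (1/2) ln 2
        assert sum_rate_bound(alloc, range(4), 0.5, 1.0) == pytest.approx(
            0.5 * math.log(2), rel=1e-12
        )
        with pytest.raises(IndexError):
            sum_rate_bound(alloc, [4], 0.5, 1.0)

    def test_full_set_equals_capacity(self):
        alloc = PowerAllocation.equal(3)
        d, t = 0.2, 1.7
        assert sum_rate_bound(alloc, range(3), d, t) == pytest.approx(
            gaussian_capacity(1.0 / (2 * d * t)), rel=1e-12
        )

    def test_per_item_rate_single_item(self):
        spec = ChannelSpec(n_items=1, n_channels=1, diffusivity=0.25, duration=2.0)
        rr = per_item_rate(spec)
        assert rr.per_use_rate == pytest.approx(gaussian_capacity(spec.snr), rel=1e-12)
        assert rr.total_rate == pytest.approx(rr.per_use_rate, rel=1e-12)

    def test_per_item_rate_halves_when_items_double(self):
        base = ChannelSpec(n_items=2, n_channels=8, diffusivity=0.25, duration=2.0)
        double = ChannelSpec(n_items=4, n_channels=8, diffusivity=0.25, duration=2.0)
        assert per_item_rate(double).per_use_rate == pytest.approx(
            per_item_rate(base).per_use_rate / 2, rel=1e-12
        )

    def test_per_item_rate_mpmath_oracle(self):
        # 1/2D = 3 s, T = 3 s, K = N = 6: total rate = N/(2K) ln(1 + 1) = ln2/2
        spec = ChannelSpec(n_items=6, n_channels=6, diffusivity=1 / 6, duration=3.0)
        expected = float(mpmath.log(2) / 2)
        assert per_item_rate(spec).total_rate == pytest.approx(expected, rel=1e-12)

    def test_zero_duration_is_error(self):
        with pytest.raises(ValueError):
            per_item_rate(ChannelSpec(n_items=2, duration=0.0))


class TestRateDistortion:
    def test_zero_rate_endpoints(self):
        b = rate_distortion_interval(0.0, phi=1.0)
        assert b.lower == pytest.approx(1 / (2 * math.pi * math.e), rel=1e-12)
        assert b.upper == pytest.approx(1 / 12, rel=1e-12)

    def test_unit_rate_scales_by_exp_minus_two(self):
        b0, b1 = rate_distortion_interval(0.0), rate_distortion_interval(1.0)
        assert b1.lower == pytest.approx(b0.lower * math.exp(-2), rel=1e-12)
        assert b1.upper == pytest.approx(b0.upper * math.exp(-2), rel=1e-12)

    @given(r=st.floats(0, 50), phi=st.floats(0.1, 10))
    def test_lower_below_upper(self, r, phi):
        b = rate_distortion_interval(r, phi)
        assert 0 <= b.lower < b.upper <= phi**2 / 12 + 1e-15

    def test_negative_rate_rejected(self):
        with pytest.raises(ValueError):
            rate_distortion_interval(-0.01)


class TestCodedBound:
    def test_mpmath_oracle(self):
        # Phi=1, 1/2D=3, T=3, N=K=6
        spec = ChannelSpec(n_items=6, n_channels=6, diffusivity=1 / 6, duration=3.0)
        with mpmath.workdps(50):
            expected = float(
                1 / (2 * mpmath.pi * mpmath.e) * (1 + mpmath.mpf(3) / 3) ** (-1)
            )
        assert coded_storage_mse_bound(spec) == pytest.approx(expected, rel=1e-12)

    def test_limits(self):
        zero_snr = ChannelSpec(n_items=4, n_channels=8, diffusivity=1.0, duration=1e12)
        assert coded_storage_mse_bound(zero_snr) == pytest.approx(
            1 / (2 * math.pi * math.e), rel=1e-6
        )
        assert coded_storage_mse_bound(ChannelSpec(duration=0.0)) == 0.0

    # ranges keep N/K * log1p(snr) < ~400 so the bound stays representable
    @given(
        d=st.floats(1e-2, 10), n=st.floats(0.5, 50), k=st.floats(1, 10), t=st.floats(0.1, 30)
    )
    def test_monotonicity(self, d, n, k, t):
        base = coded_storage_mse_bound(
            ChannelSpec(n_items=k, n_channels=n, diffusivity=d, duration=t)
        )
        more_channels = coded_storage_mse_bound(
            ChannelSpec(n_items=k, n_channels=2 * n, diffusivity=d, duration=t)
        )
        longer = coded_storage_mse_bound(
            ChannelSpec(n_items=k, n_channels=n, diffusivity=d, duration=2 * t)
        )
        more_items = coded_storage_mse_bound(
            ChannelSpec(n_items=2 * k, n_channels=n, diffusivity=d, duration=t)
        )
        assert more_channels < base < longer
        assert base < more_items
        assert base <= 1 / (2 * math.pi * math.e) + 1e-15

    def test_compositional_identity_on_grid(self):
        """Bound == rate-distortion lower end at the per-item total rate."""
        rel_errs = []
        for d in np.logspace(-2, 1, 10):
            for n in np.logspace(0, 2, 10):
                for k in (1, 2, 4, 6, 8):
                    for t in (0.1, 1.0, 3.0):
                        spec = ChannelSpec(
                            n_items=k, n_channels=n, diffusivity=d, duration=t
                        )
                        direct = coded_storage_mse_bound(spec)
                        via_rd = rate_distortion_interval(
                            per_item_rate(spec).total_rate, spec.phi
                        ).lower
                        rel_errs.append(abs(direct - via_rd) / via_rd)
        assert len(rel_errs) >= 1000
        assert max(rel_errs) < 1e-12

    def test_log_domain_matches_naive(self):
        for n_over_k in (0.5, 2, 20):
            for snr in (1e-6, 1.0, 1e6):
                naive = 1 / (2 * math.pi * math.e) * (1 + snr) ** (-n_over_k)
                spec = ChannelSpec(
                    n_items=1, n_channels=n_over_k, diffusivity=1.0, duration=1 / (2 * snr)
                )
                assert coded_storage_mse_bound(spec) == pytest.approx(naive, rel=1e-10)

    def test_grid_matches_scalar(self):
        n = np.array([[2.0], [10.0]])
        v = np.array([[0.5, 2.28]])
        grid = coded_storage_mse_grid(n, v, n_items=4, duration=2.0)
        for i in range(2):
            for j in range(2):
                spec = ChannelSpec(
                    n_items=4,
                    n_channels=float(n[i, 0]),
                    diffusivity=1 / (2 * v[0, j]),
                    duration=2.0,
                )
                assert grid[i, j] == pytest.approx(
                    coded_storage_mse_bound(spec), rel=1e-12
                )


class TestHeuristicIdentityAndResource:
    @given(snr=st.floats(0, 1e6), n=positive, k=st.floats(1, 20))
    def test_identity_holds(self, snr, n, k):
        assert heuristic_identity_check(snr, n, k)

    def test_hand_value(self):
        # snr=1, N/K=2: both sides 1/4
        assert math.exp(-2 * 2 * gaussian_capacity(1.0)) == pytest.approx(0.25, rel=1e-12)

    def test_resource(self):
        assert resource(5, 6.4) == pytest.approx(32.0)
        assert resource(1, 7.7) == pytest.approx(7.7)
        assert resource(10, 3.2) == pytest.approx(resource(5, 6.4), rel=1e-12)

    @given(x=positive)
    def test_unit_conversions_inverse(self, x):
        assert deg2_to_norm(norm_to_deg2(x)) == pytest.approx(x, rel=1e-12)
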