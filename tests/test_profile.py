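import numpy as np
import pytest
from scipy import stats

from palmcount import (
    CalibrationProfile,
    aggregate_profile,
    build_calibration,
    calibrate,
    compare_groups,
    compute_density,
    make_measurement,
    weighted_mean,
)


def meas(depth, density, error, fov="f", area=100.0, replicate=0):
    """Measurement with a prescribed density and error."""
    m = make_measurement(
        fov_id=fov,
        depth_um=depth,
        raw_count=density * area,
        predicted_spurious=0.0,
        corrected_count=density * area,
        area_um2=area,
        replicate=replicate,
    )
    m.density, m.density_error = density, error
    return m


class TestDensity:
    def test_zero_count(self):
        assert compute_density(0.0, 10.0) == (0.0, 0.0)

    def test_poisson_error(self):
        density, error = compute_density(400.0, 100.0)
        assert density == pytest.approx(4.0)
        assert error == pytest.approx(0.2)

    def test_zero_area_flagged_invalid(self):
        m = make_measurement("f", 0.0, 10, 0, 10, 0.0)
        assert not m.valid
        assert "zero_area" in m.flags
        with pytest.raises(ValueError):
            compute_density(10.0, 0.0)


class TestCalibration:
    def test_identical_densities_give_unit_factors(self):
        ms = [meas(z, 5.0, 0.5) for z in (0.0, 4.5, 9.0, 13.5)]
        profile = build_calibration(ms)
        assert profile.factors == pytest.approx((1.0, 1.0, 1.0, 1.0))

    def test_factor_arithmetic(self):
        ms = [
            meas(z, d, 0.1)
            for z, d in zip((0.0, 4.5, 9.0, 13.5), (10.0, 8.0, 6.0, 5.0))
        ]
        profile = build_calibration(ms)
        assert profile.depths_um == (0.0, 4.5, 9.0, 13.5)
        assert profile.factors == pytest.approx((1.0, 0.8, 0.6, 0.5))

    def test_missing_depth0_rejected(self):
        with pytest.raises(ValueError, match="depth 0"):
            build_calibration([meas(4.5, 5.0, 0.5)])

    def test_calibrate_arithmetic(self):
        profile = CalibrationProfile(
            (0.0, 4.5, 9.0, 13.5), (1.0, 0.8, 0.6, 0.5), (0.0, 0.0, 0.0, 0.0)
        )
        ms = [
            meas(z, d, 0.01)
            for z, d in zip((0.0, 4.5, 9.0, 13.5), (1.0, 0.4, 0.1, 0.02))
        ]
        out = calibrate(ms, profile)
        assert [m.density for m in out] == pytest.approx([1.0, 0.5, 0.1 / 0.6, 0.04])

    def test_unit_factors_are_identity(self):
        profile = CalibrationProfile((0.0,), (1.0,), (0.0,))
        ms = [meas(0.0, 3.3, 0.2)]
        out = calibrate(ms, profile)
        assert out[0].density == pytest.approx(3.3)
        assert out[0].density_error == pytest.approx(0.2)

    def test_unknown_depth_named_in_error(self):
        profile = CalibrationProfile((0.0,), (1.0,), (0.0,))
        with pytest.raises(KeyError, match="9.0"):
            calibrate([meas(9.0, 1.0, 0.1)], profile)

    def test_self_consistency(self):
        """Calibrating a sample by its own profile flattens it to 1."""
        rng = np.random.default_rng(3)
        ms = [
            meas(z, d * (1 + 0.1 * rng.standard_normal()), 0.1 * d, fov=f"f{i}")
            for z, d in zip((0.0, 4.5, 9.0, 13.5), (10.0, 7.0, 4.0, 2.0))
            for i in range(5)
        ]
        profile = build_calibration(ms)
        flat = build_calibration(calibrate(ms, profile))
        assert flat.factors == pytest.approx((1.0, 1.0, 1.0, 1.0), abs=1e-12)


class TestAggregation:
    def test_identical_measurements(self):
        ms = [meas(0.0, 4.0, 0.2) for _ in range(4)]
        profile = aggregate_profile(ms)
        assert profile.mean_density[0] == pytest.approx(4.0)
        assert profile.mean_error[0] == pytest.approx(0.2 / 2.0)

    def test_inverse_variance_example(self):
        mean, err = weighted_mean([4.0, 6.0], [0.2, 0.6])
        assert mean == pytest.approx(4.2)
        assert err == pytest.approx(0.18974, abs=1e-4)

    def test_equal_weights_mode_is_arithmetic_mean(self):
        ms = [meas(0.0, d, 0.1 * (i + 1)) for i, d in enumerate((2.0, 4.0, 9.0))]
        profile = aggregate_profile(ms, weighting="equal")
        assert profile.mean_density[0] == pytest.approx(5.0)

    def test_weighted_mean_within_bounds_and_monotone(self, rng):
        for _ in range(20):
            vals = rng.uniform(1, 10, 5)
            errs = rng.uniform(0.1, 2.0, 5)
            mean, _ = weighted_mean(vals, errs)
            assert vals.min() - 1e-12 <= mean <= vals.max() + 1e-12
            # shrinking one error pulls the mean toward that value
            k = int(rng.integers(0, 5))
            errs2 = errs.copy()
            errs2[k] /= 10.0
            mean2, _ = weighted_mean(vals, errs2)
            assert abs(mean2 - vals[k]) <= abs(mean - vals[k]) + 1e-12

    def test_invalid_measurements_excluded(self):
        good = meas(0.0, 4.0, 0.2)
        bad = make_measurement("f", 0.0, 10, 0, 10, 0.0)
        profile = aggregate_profile([good, bad])
        assert profile.n_fov == (1,)

    def test_normalized_profile(self):
        ms = [meas(0.0, 8.0, 0.1), meas(4.5, 4.0, 0.1)]
        norm = aggregate_profile(ms).normalized()
        assert norm.mean_density == pytest.approx((1.0, 0.5))


class TestCompareGroups:
    def test_identical_groups(self):
        t, p = compare_groups([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert p > 0.9
        assert t == pytest.approx(0.0)

    def test_shifted_groups_strongly_significant(self):
        a = [1.0, 1.001, 1.002]  # tiny within-group variance
        b = [11.0, 11.001, 11.002]
        _t, p = compare_groups(a, b)
        assert p < 1e-4

    def test_matches_textbook_formula(self, rng):
        """Equal-variance t computed by hand agrees to 1e-10."""
        a = rng.normal(0, 1, 12)
        b = rng.normal(0.5, 1, 9)
        t, p = compare_groups(a, b)
        na, nb = len(a), len(b)
        sp2 = ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / (na + nb - 2)
        t_hand = (a.mean() - b.mean()) / np.sqrt(sp2 * (1 / na + 1 / nb))
        p_hand = 2 * stats.t.sf(abs(t_hand), na + nb - 2)
        assert t == pytest.approx(t_hand, abs=1e-10)
        assert p == pytest.approx(p_hand, abs=1e-10)

    def test_small_groups_rejected(self):
        with pytest.raises(ValueError):
            compare_groups([1.0], [1.0, 2.0])
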