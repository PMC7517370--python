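import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ehgphase import (
    DegenerateSignalError,
    InsufficientLengthError,
    ParameterError,
    SODP,
    SectorProfile,
    Signal,
    build_sodp,
    default_k_grid,
    phase_entropy,
    phen_curve,
    sector_profile,
    slope_angle,
)

from oracles import straight_line_phen

TWO_PI = 2.0 * math.pi


class TestBuildSODP:
    def test_forced_points(self):
        sodp = build_sodp(Signal(np.array([1.0, 2, 4, 7, 11]), fs=20))
        assert np.array_equal(sodp.x, [1, 2, 3])
        assert np.array_equal(sodp.y, [2, 3, 4])
        assert sodp.n_excluded == 0

    def test_constant_series_degenerate(self):
        with pytest.raises(DegenerateSignalError):
            build_sodp(Signal(np.array([5.0, 5, 5, 5]), fs=20))

    def test_too_short(self):
        with pytest.raises(InsufficientLengthError):
            build_sodp(Signal(np.array([1.0, 2.0]), fs=20))

    def test_origin_points_excluded_and_counted(self):
        # the two repeated values make one (0, 0) point
        sodp = build_sodp(Signal(np.array([1.0, 2, 2, 2, 3]), fs=20))
        assert sodp.n_excluded == 1
        assert len(sodp) + sodp.n_excluded == 5 - 2

    def test_matches_per_index_loop(self, rng):
        values = rng.standard_normal(100)
        sodp = build_sodp(Signal(values, fs=20))
        assert len(sodp) == 98
        for i in range(98):
            assert sodp.x[i] == values[i + 1] - values[i]
            assert sodp.y[i] == values[i + 2] - values[i + 1]
            t = math.atan2(sodp.y[i], sodp.x[i]) % TWO_PI
            assert sodp.theta[i] == pytest.approx(t, abs=1e-15)

    def test_theta_range(self, gaussian_signal):
        theta = build_sodp(gaussian_signal).theta
        assert np.all((theta >= 0.0) & (theta < TWO_PI))


class TestSlopeAngle:
    @pytest.mark.parametrize(
        "x,y,expected",
        [
            (1, 0, 0.0),
            (0, 1, math.pi / 2),
            (-1, 0, math.pi),
            (0, -1, 3 * math.pi / 2),
            (1, 1, math.pi / 4),
            (-2, -2, 5 * math.pi / 4),
        ],
    )
    def test_axis_and_quadrant_cases(self, x, y, expected):
        assert slope_angle(x, y) == pytest.approx(expected, abs=1e-15)

    def test_origin_rejected(self):
        with pytest.raises(DegenerateSignalError):
            slope_angle(0.0, 0.0)


def _sodp_from_angles(angles):
    angles = np.asarray(angles, float)
    return SODP(x=np.cos(angles), y=np.sin(angles), theta=angles)


class TestSectorProfile:
    def test_four_quadrant_weighting(self):
        angles = [math.pi / 4, 3 * math.pi / 4, 5 * math.pi / 4, 7 * math.pi / 4]
        prof = sector_profile(_sodp_from_angles(angles), k=4)
        assert np.array_equal(prof.counts, [1, 1, 1, 1])
        assert np.allclose(prof.s_theta, angles)
        # total angle mass 4*pi; later sectors carry more weight
        assert np.allclose(prof.p, [1 / 16, 3 / 16, 5 / 16, 7 / 16])

    def test_single_occupied_sector(self, rng):
        angles = rng.uniform(0, math.pi / 2 - 1e-9, size=50)
        prof = sector_profile(_sodp_from_angles(angles), k=4)
        assert np.allclose(prof.p, [1, 0, 0, 0])

    def test_brute_force_accumulation(self, rng):
        angles = rng.uniform(0, TWO_PI, size=100)
        k = 8
        prof = sector_profile(_sodp_from_angles(angles), k)
        s = np.zeros(k)
        counts = np.zeros(k, dtype=int)
        for t in angles:
            i = min(int(math.floor(t * k / TWO_PI)), k - 1)
            s[i] += t
            counts[i] += 1
        assert np.array_equal(prof.counts, counts)
        assert np.allclose(prof.s_theta, s, atol=1e-12)
        assert np.allclose(prof.p, s / s.sum(), atol=1e-12)

    def test_probabilities_sum_to_one(self, gaussian_signal):
        sodp = build_sodp(gaussian_signal)
        for k in default_k_grid():
            prof = sector_profile(sodp, k)
            assert prof.counts.sum() == len(sodp)
            assert abs(prof.p.sum() - 1.0) < 1e-12
            assert np.all(prof.p >= 0) and np.all(prof.s_theta >= 0)

    def test_running_sum_variant_is_not_a_distribution(self, gaussian_signal):
        sodp = build_sodp(gaussian_signal)
        prof = sector_profile(sodp, 8, normalization="running")
        assert prof.p.sum() != pytest.approx(1.0, abs=1e-6)
        assert prof.p[0] == pytest.approx(1.0)  # first ratio is S1/S1

    def test_invalid_k(self, gaussian_signal):
        with pytest.raises(ParameterError):
            sector_profile(build_sodp(gaussian_signal), 1)


def _profile_from_p(p):
    p = np.asarray(p, float)
    return SectorProfile(k=len(p), s_theta=p, counts=np.ones(len(p), int), p=p)


class TestPhaseEntropy:
    def test_concentrated_distribution_is_zero(self):
        assert phase_entropy(_profile_from_p([1, 0, 0, 0])) == 0.0

    def test_uniform_distribution_is_one(self):
        for k in (4, 8, 36):
            assert phase_entropy(_profile_from_p(np.full(k, 1 / k))) == pytest.approx(
                1.0, abs=1e-12
            )

    def test_weighted_quadrant_value(self):
        p = np.array([1, 3, 5, 7]) / 16
        expected = -float(np.sum(p * np.log(p))) / math.log(4)
        value = phase_entropy(_profile_from_p(p))
        assert value == pytest.approx(expected, abs=1e-15)
        assert value == pytest.approx(0.874, abs=5e-4)

    def test_log_base_cancels(self):
        p = np.array([0.1, 0.2, 0.3, 0.4])
        base2 = -float(np.sum(p * np.log2(p))) / math.log2(4)
        assert phase_entropy(_profile_from_p(p)) == pytest.approx(base2, abs=1e-12)

    def test_bounds_on_random_profiles(self, rng):
        for _ in range(1000):
            k = int(rng.integers(2, 40))
            w = rng.random(k)
            p = w / w.sum()
            assert 0.0 <= phase_entropy(_profile_from_p(p)) <= 1.0 + 1e-12


class TestPhEnCurve:
    def test_default_grid(self, gaussian_signal):
        curve = phen_curve(gaussian_signal)
        assert curve.k_values == (4, 8, 12, 16, 20, 24, 28, 32, 36)
        assert len(curve.phen) == 9
        assert np.all((curve.phen >= 0) & (curve.phen <= 1))

    def test_amplitude_doubling_invariance(self, gaussian_signal):
        doubled = gaussian_signal.replace(values=2.0 * gaussian_signal.values)
        assert np.array_equal(
            phen_curve(gaussian_signal).phen, phen_curve(doubled).phen
        )

    def test_matches_straight_line_oracle(self, rng):
        values = rng.standard_normal(300)
        curve = phen_curve(Signal(values, fs=20))
        for k, v in zip(curve.k_values, curve.phen):
            assert v == pytest.approx(straight_line_phen(values, k), abs=1e-12)

    def test_angle_unit_cancels(self, rng):
        values = rng.standard_normal(300)
        for k in (4, 16):
            assert straight_line_phen(values, k) == pytest.approx(
                straight_line_phen(values, k, degrees=True), abs=1e-12
            )

    @given(
        a=st.floats(1e-3, 1e3),
        b=st.floats(-100.0, 100.0),
        seed=st.integers(0, 2**16),
    )
    @settings(max_examples=25, deadline=None)
    def test_affine_invariance(self, a, b, seed):
        values = np.random.default_rng(seed).standard_normal(200)
        base = phen_curve(Signal(values, fs=20)).phen
        transformed = phen_curve(Signal(a * values + b, fs=20)).phen
        assert np.allclose(base, transformed, atol=1e-12)

    def test_concentration_iff_single_sector(self, rng):
        # all angles in one sector -> PhEn 0; two sectors occupied -> > 0
        one = sector_profile(_sodp_from_angles(rng.uniform(0.0, 0.3, 40)), 4)
        two = sector_profile(
            _sodp_from_angles(np.r_[rng.uniform(0.0, 0.3, 20), rng.uniform(2.0, 2.3, 20)]),
            4,
        )
        assert phase_entropy(one) == 0.0
        assert phase_entropy(two) > 0.0
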