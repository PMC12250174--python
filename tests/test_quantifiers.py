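import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import oracles
from neomotion import (
    CovarianceModel,
    InsufficientDataError,
    ParameterError,
    UnknownMethodError,
    fit_covariance,
    step_chebyshev,
    step_euclidean,
    step_mahalanobis,
    step_manhattan,
    step_minkowski,
    total_motion,
)
from neomotion.quantifiers import (
    METHOD_NAMES,
    angular_displacement,
    differential_acceleration,
    lucas_kanade_motion,
)

from conftest import make_seq

finite_delta = st.tuples(
    *[st.floats(-5, 5, allow_nan=False) for _ in range(3)]
)


class TestStepMetrics:
    @pytest.mark.parametrize(
        "fn,d,expected",
        [
            (step_euclidean, (0, 0, 0), 0.0),
            (step_euclidean, (1, 2, 2), 3.0),
            (step_euclidean, (0.3, 0.4, 0), 0.5),
            (step_manhattan, (0, 0, 0), 0.0),
            (step_manhattan, (1, -2, 2), 5.0),
            (step_chebyshev, (1, -2, 2), 2.0),
            (step_chebyshev, (0, 0, 0), 0.0),
        ],
    )
    def test_hand_values(self, fn, d, expected):
        assert fn(np.array(d)) == pytest.approx(expected, abs=1e-15)

    @settings(derandomize=True, max_examples=200)
    @given(finite_delta)
    def test_norm_ordering(self, d):
        d = np.array(d)
        assert step_chebyshev(d) <= step_euclidean(d) + 1e-12
        assert step_euclidean(d) <= step_manhattan(d) + 1e-12

    @settings(derandomize=True, max_examples=100)
    @given(finite_delta)
    def test_minkowski_reduces_to_manhattan_and_euclidean(self, d):
        d = np.array(d)
        assert step_minkowski(d, 1) == pytest.approx(step_manhattan(d), rel=1e-12, abs=1e-12)
        assert step_minkowski(d, 2) == pytest.approx(step_euclidean(d), rel=1e-12, abs=1e-12)

    def test_minkowski_large_p_approaches_chebyshev(self):
        d = np.array([1.0, -2.0, 2.0])
        assert step_minkowski(d, 64) == pytest.approx(2.0, rel=2e-2)
        assert step_minkowski(d, 64) >= 2.0

    def test_minkowski_rejects_p_below_one(self):
        with pytest.raises(ParameterError):
            step_minkowski(np.ones(3), 0.5)


class TestCovariance:
    def test_isotropic_samples_recover_scaled_identity(self, rng):
        sigma = 0.3
        coords = sigma * rng.standard_normal((2000, 10, 3))
        model = fit_covariance(coords)
        np.testing.assert_allclose(model.S, sigma**2 * np.eye(3), atol=0.1 * sigma**2)

    def test_identical_samples_fall_back_to_identity(self):
        coords = np.full((10, 5, 3), 0.7)
        model = fit_covariance(coords)
        assert model.degenerate
        np.testing.assert_array_equal(model.S, np.eye(3))

    def test_collinear_samples_get_ridge(self, rng):
        line = rng.standard_normal((500, 1))
        coords = (line * np.array([1.0, 2.0, -1.0]))[:, None, :]
        model = fit_covariance(coords)
        assert model.ridge > 0
        # regularized matrix is invertible: whitening succeeds
        assert np.isfinite(model.whiten(np.ones(3))).all()

    def test_too_few_frames(self, rng):
        seq = make_seq(0.5 + 0.01 * rng.standard_normal((3, 33, 3)))
        with pytest.raises(InsufficientDataError):
            fit_covariance(seq)


class TestMahalanobis:
    def test_identity_covariance_equals_euclidean(self, rng):
        d = rng.standard_normal((50, 3))
        cov = CovarianceModel(np.eye(3))
        np.testing.assert_allclose(step_mahalanobis(d, cov), step_euclidean(d), rtol=1e-12)

    def test_scaled_identity(self):
        cov = CovarianceModel(4 * np.eye(3))
        assert step_mahalanobis(np.array([1.0, 2.0, 2.0]), cov) == pytest.approx(1.5)

    def test_matches_explicit_inverse_oracle(self, rng):
        A = rng.standard_normal((3, 3))
        S = A @ A.T + 0.5 * np.eye(3)
        cov = CovarianceModel(S)
        inv = np.linalg.inv(S)
        for d in rng.standard_normal((20, 3)):
            expected = np.sqrt(d @ inv @ d)
            assert step_mahalanobis(d, cov) == pytest.approx(expected, rel=1e-10)


class TestTotalMotion:
    def test_constant_sequence_is_zero_for_every_method(self, constant_seq):
        for m in METHOD_NAMES:
            params = None
            if m == "farneback":
                params = {"render": {"size": 48, "radius": 2},
                          "flow": {"levels": 1, "iterations": 1, "winsize": 9}}
            t = total_motion(constant_seq, m, params)
            assert t.value <= 1e-9, m

    def test_three_four_five_triangle(self):
        coords = np.array([[[0.1, 0.1, 0.0]], [[0.4, 0.5, 0.0]]])
        seq = make_seq(coords, landmark_indices=[0])
        assert total_motion(seq, "euclidean").value == pytest.approx(0.5)
        assert total_motion(seq, "euclidean").n_steps == 1

    @pytest.mark.parametrize("method", ["euclidean", "manhattan", "chebyshev", "minkowski"])
    def test_pairwise_oracle_equivalence(self, method, rng):
        coords = 0.5 + 0.05 * rng.standard_normal((10, 7, 3))
        seq = make_seq(coords, landmark_indices=range(7))
        expected = oracles.pairwise_total(coords, method, p=3.0)
        assert total_motion(seq, method).value == pytest.approx(expected, rel=1e-12)

    def test_translation_invariance(self, random_seq):
        shifted = make_seq(random_seq.coords + np.array([0.01, -0.02, 0.3]))
        for m in ("euclidean", "manhattan", "chebyshev", "minkowski", "mahalanobis"):
            a = total_motion(random_seq, m).value
            b = total_motion(shifted, m).value
            assert b == pytest.approx(a, rel=1e-9), m

    def test_additivity_over_shared_boundary(self, random_seq):
        n = len(random_seq)
        k = 11
        for m in ("euclidean", "manhattan", "chebyshev", "minkowski"):
            whole = total_motion(random_seq, m).value
            left = total_motion(random_seq.slice(0, k + 1), m).value
            right = total_motion(random_seq.slice(k, n), m).value
            assert left + right == pytest.approx(whole, rel=1e-12), m

    def test_too_few_frames(self):
        seq1 = make_seq(np.full((2, 33, 3), 0.5))
        with pytest.raises(InsufficientDataError):
            total_motion(seq1, "angular")
        with pytest.raises(InsufficientDataError):
            total_motion(make_seq(np.full((3, 33, 3), 0.5)).slice(0, 1), "euclidean")

    def test_unknown_method(self, random_seq):
        with pytest.raises(UnknownMethodError):
            total_motion(random_seq, "fourier")

    def test_gap_transitions_excluded(self, rng):
        coords = 0.5 + 0.01 * rng.standard_normal((10, 33, 3))
        ts = 1_000_000 + 100 * np.arange(10, dtype=np.int64)
        ts[5:] += 10_000  # dropout between frames 4 and 5
        from neomotion.pose_io import LandmarkSequence
        seq = LandmarkSequence("gap", ts, coords)
        t = total_motion(seq, "euclidean")
        assert t.n_steps == 8
        assert t.n_excluded == 1


class TestDifferentialAcceleration:
    def test_uniform_velocity_is_zero(self):
        coords = np.linspace(0.2, 0.6, 8)[:, None, None] * np.ones((1, 4, 3))
        t = differential_acceleration(make_seq(coords, landmark_indices=range(4)))
        assert t.value == pytest.approx(0.0, abs=1e-12)

    def test_hand_example(self):
        coords = np.zeros((3, 1, 3))
        coords[2, 0, 0] = 1.0
        seq = make_seq(coords, landmark_indices=[0])
        t = differential_acceleration(seq, fps=10.0)
        assert t.value == pytest.approx(10.0)
        assert t.n_steps == 1

    def test_oracle_equivalence(self, rng):
        coords = 0.5 + 0.03 * rng.standard_normal((12, 5, 3))
        seq = make_seq(coords, landmark_indices=range(5))
        expected = oracles.diffacc_total(coords, seq.fps)
        assert differential_acceleration(seq).value == pytest.approx(expected, rel=1e-12)

    def test_invalid_fps(self, random_seq):
        with pytest.raises(ParameterError):
            differential_acceleration(random_seq, fps=-1.0)


class TestAngularDisplacement:
    def test_collinear_motion_is_zero(self):
        coords = np.linspace(0.1, 0.9, 9)[:, None, None] * np.ones((1, 2, 3))
        t = angular_displacement(make_seq(coords, landmark_indices=[0, 1]))
        assert t.value == pytest.approx(0.0, abs=1e-7)

    def test_right_angle_turn(self):
        coords = np.array([[[0.2, 0.2, 0.0]], [[0.4, 0.2, 0.0]], [[0.4, 0.4, 0.0]]])
        t = angular_displacement(make_seq(coords, landmark_indices=[0]))
        assert t.value == pytest.approx(np.pi / 2, rel=1e-12)

    def test_zero_length_segment_contributes_zero(self):
        coords = np.array([[[0.2, 0.2, 0.0]], [[0.2, 0.2, 0.0]], [[0.4, 0.4, 0.0]]])
        t = angular_displacement(make_seq(coords, landmark_indices=[0]))
        assert t.value == pytest.approx(0.0, abs=1e-15)

    def test_atan2_oracle_equivalence(self, rng):
        coords = 0.5 + 0.04 * rng.standard_normal((15, 6, 3))
        seq = make_seq(coords, landmark_indices=range(6))
        expected = oracles.angular_total(coords)
        assert angular_displacement(seq).value == pytest.approx(expected, abs=1e-9)


class TestLucasKanade:
    def test_constant_sequence_is_zero(self, constant_seq):
        assert lucas_kanade_motion(constant_seq).value == 0.0

    def test_uniform_translation_constant_per_stencil(self):
        step = np.array([0.01, 0.005, 0.002])
        coords = 0.3 + np.arange(8)[:, None, None] * step[None, None, :]
        seq = make_seq(np.tile(coords, (1, 3, 1)), landmark_indices=range(3))
        from neomotion.quantifiers import step_series
        series = step_series(seq, "lucas_kanade")
        assert np.all(series.values > 0)
        np.testing.assert_allclose(series.values, series.values[0], rtol=1e-12)

    def test_pseudoinverse_oracle_equivalence(self, rng):
        coords = 0.5 + 0.02 * rng.standard_normal((14, 4, 3))
        seq = make_seq(coords, landmark_indices=range(4))
        expected = oracles.lucas_kanade_total(coords)
        assert lucas_kanade_motion(seq).value == pytest.approx(expected, rel=1e-9)
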