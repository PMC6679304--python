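"""Time-domain features, sliding windows, and training-set assembly."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

import emgrt
from emgrt.features import (WindowSpec, activity_centered, batch_features,
                            build_training_set, hjorth, mav, rms,
                            sliding_windows, ssc, ssc_count, wl,
                            window_features)
from emgrt.preprocess import PreprocessedSignal, preprocess
from emgrt.synth import generate_repetition

# ---------------------------------------------------------------- examples


@pytest.mark.parametrize("func, window, expected", [
    (mav, [0.2, 0.4, 0.6], 0.4),
    (mav, [0.0, 0.0, 0.0], 0.0),
    (mav, [-1, 1, -1, 1], 1.0),
    (rms, [0.7, 0.7, 0.7], 0.7),
    (rms, [-0.7, -0.7], 0.7),
    (rms, [3.0, 4.0], np.sqrt(25.0 / 2.0)),
    (rms, [0.0, 0.0], 0.0),
    (ssc, [1.0, 3.0, 2.0, 4.0], 4.0),     # |2*1| + |-1*-2|
    (ssc, [0.0, 1.0, 2.0, 3.0], 2.0),     # monotone ramp: |1*-1| twice
    (ssc, [5.0, 5.0, 5.0], 0.0),
    (wl, [0.0, 1.0, 0.5], 1.5),
    (wl, [2.0, 2.0, 2.0], 0.0),
    (wl, [0.0, -1.0, 1.0], 3.0),
])
def test_feature_hand_computed_values(func, window, expected):
    assert func(np.array(window, dtype=float)) == pytest.approx(expected)


@pytest.mark.parametrize("func, min_len", [
    (mav, 1), (rms, 1), (ssc, 3), (wl, 2), (hjorth, 3),
])
def test_feature_minimum_window_length(func, min_len):
    with pytest.raises(ValueError, match="at least"):
        func(np.zeros(min_len - 1))


def test_ssc_count_variant_counts_sign_changes():
    # slopes: +2, -1, +2, -1 -> sign changes at every interior sample
    assert ssc_count(np.array([1.0, 3.0, 2.0, 4.0, 3.0])) == 3
    assert ssc_count(np.array([0.0, 1.0, 2.0, 3.0])) == 0


class TestHjorth:
    def test_complexity_of_pure_sine_is_one(self):
        t = np.arange(400) / 200.0
        s = np.sin(2 * np.pi * 5.0 * t)
        _, _, complexity = hjorth(s)
        assert complexity == pytest.approx(1.0, rel=0.01)

    def test_mobility_of_sine_matches_closed_form(self):
        """First-difference mobility of sin(omega k) is 2 sin(omega / 2)."""
        t = np.arange(400) / 200.0
        s = np.sin(2 * np.pi * 5.0 * t)
        _, mobility, _ = hjorth(s)
        omega = 2 * np.pi * 5.0 / 200.0
        assert mobility == pytest.approx(2 * np.sin(omega / 2), rel=0.02)

    def test_complexity_ordering_sine_noise_random_walk(self):
        """Complexity is minimized (at 1) by a pure sinusoid; white noise
        sits slightly above 1, and integrated noise — whose derivative is
        much rougher than the signal itself — is far larger.  Verified by
        direct computation on seeded draws."""
        t = np.arange(200) / 200.0
        *_, c_sine = hjorth(np.sin(2 * np.pi * 5.0 * t))
        for seed in range(5):
            noise = np.random.default_rng(seed).normal(size=200)
            *_, c_noise = hjorth(noise)
            *_, c_walk = hjorth(np.cumsum(noise))
            assert c_sine < c_noise < c_walk

    def test_activity_is_uncentered_power(self):
        x = np.array([1.0, 1.0, 1.0, 1.0])
        a, _, _ = hjorth(x + np.array([0.0, 0.1, -0.1, 0.0]))
        assert a == pytest.approx(np.sum((x + [0, .1, -.1, 0]) ** 2) / 3)
        # centered variant subtracts the mean
        assert activity_centered(x) == 0.0

    def test_constant_window_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            hjorth(np.zeros(10))

    def test_zero_derivative_variance_gives_zero_complexity(self):
        a, m, c = hjorth(np.full(10, 3.0))
        assert m == 0.0 and c == 0.0


# -------------------------------------------------- oracle and properties

def _naive_features(x):
    """Literal-loop transcription of the five feature definitions."""
    n = len(x)
    out = {}
    out["mav"] = sum(abs(x[k]) for k in range(n)) / n
    out["rms"] = (sum(x[k] ** 2 for k in range(n)) / n) ** 0.5
    out["ssc"] = sum(abs((x[k] - x[k - 1]) * (x[k] - x[k + 1]))
                     for k in range(1, n - 1))
    out["wl"] = sum(abs(x[k] - x[k - 1]) for k in range(1, n))
    var_s = sum(v ** 2 for v in x) / (n - 1)
    d1 = [x[k] - x[k - 1] for k in range(1, n)]
    var_d1 = sum(v ** 2 for v in d1) / (len(d1) - 1)
    d2 = [d1[k] - d1[k - 1] for k in range(1, len(d1))]
    var_d2 = sum(v ** 2 for v in d2) / max(len(d2) - 1, 1)
    out["activity"] = var_s
    out["mobility"] = (var_d1 / var_s) ** 0.5
    out["complexity"] = (var_d2 / var_d1) ** 0.5 / out["mobility"]
    return out


def test_features_match_literal_loop_oracle():
    rng = np.random.default_rng(99)
    for _ in range(50):
        x = rng.normal(size=rng.integers(5, 120))
        ref = _naive_features(list(x))
        a, m, c = hjorth(x)
        assert mav(x) == pytest.approx(ref["mav"], rel=1e-9)
        assert rms(x) == pytest.approx(ref["rms"], rel=1e-9)
        assert ssc(x) == pytest.approx(ref["ssc"], rel=1e-9)
        assert wl(x) == pytest.approx(ref["wl"], rel=1e-9)
        assert a == pytest.approx(ref["activity"], rel=1e-9)
        assert m == pytest.approx(ref["mobility"], rel=1e-9)
        assert c == pytest.approx(ref["complexity"], rel=1e-9)


@given(st.integers(0, 2 ** 31), st.floats(0.01, 100.0))
def test_feature_scaling_covariance(seed, alpha):
    """Scaling the window by alpha scales MAV/RMS/WL linearly, SSC and
    activity quadratically, and leaves mobility and complexity unchanged."""
    rng = np.random.default_rng(seed)
    x = rng.normal(size=40)
    a0, m0, c0 = hjorth(x)
    a1, m1, c1 = hjorth(alpha * x)
    assert mav(alpha * x) == pytest.approx(alpha * mav(x), rel=1e-9)
    assert rms(alpha * x) == pytest.approx(alpha * rms(x), rel=1e-9)
    assert wl(alpha * x) == pytest.approx(alpha * wl(x), rel=1e-9)
    assert ssc(alpha * x) == pytest.approx(alpha ** 2 * ssc(x), rel=1e-9)
    assert a1 == pytest.approx(alpha ** 2 * a0, rel=1e-9)
    assert m1 == pytest.approx(m0, rel=1e-9)
    assert c1 == pytest.approx(c0, rel=1e-9)


@given(st.integers(0, 2 ** 31))
def test_rms_dominates_mav(seed):
    rng = np.random.default_rng(seed)
    x = rng.normal(size=30)
    assert rms(x) >= mav(x) - 1e-15
    c = abs(float(rng.normal())) + 0.1
    signs = rng.choice([-1.0, 1.0], size=30)
    assert rms(signs * c) == pytest.approx(mav(signs * c), rel=1e-12)


# ------------------------------------------------------- window machinery

class TestWindowFeatures:
    def test_feature_matrix_shape_and_flat_length(self):
        rng = np.random.default_rng(1)
        fw = window_features(rng.normal(size=(80, 8)))
        assert fw.D.shape == (87, 8)
        assert fw.flat.shape == (696,)

    def test_flat_is_channel_major(self):
        rng = np.random.default_rng(2)
        fw = window_features(rng.normal(size=(10, 4)))
        np.testing.assert_array_equal(
            fw.flat.reshape(4, 17).T, fw.D)

    def test_channel_permutation_permutes_columns(self):
        rng = np.random.default_rng(3)
        w = rng.normal(size=(20, 8))
        perm = rng.permutation(8)
        np.testing.assert_allclose(window_features(w[:, perm]).D,
                                   window_features(w).D[:, perm])

    def test_all_zero_window_rejected_as_degenerate(self):
        with pytest.raises(ValueError, match="degenerate"):
            window_features(np.zeros((20, 8)))


class TestSlidingWindows:
    @pytest.mark.parametrize("length, l, stride, expected", [
        (100, 80, 1, 21),
        (80, 80, 1, 1),
        (79, 80, 1, 0),
        (100, 10, 7, 13),
    ])
    def test_window_count(self, length, l, stride, expected):
        spec = WindowSpec(length_samples=l, stride_samples=stride)
        wins = list(sliding_windows(np.zeros((length, 2)), spec))
        assert len(wins) == expected
        assert spec.count(length) == expected

    @given(st.integers(0, 300), st.integers(3, 50), st.integers(1, 10))
    def test_count_formula(self, length, l, stride):
        spec = WindowSpec(length_samples=l, stride_samples=stride)
        wins = list(sliding_windows(np.zeros((length, 1)), spec))
        expected = 0 if length < l else (length - l) // stride + 1
        assert len(wins) == expected
        for start, w in wins:
            assert w.shape[0] == l
            assert start + l <= length

    def test_batch_features_agree_with_per_window_path(self):
        rng = np.random.default_rng(8)
        env = rng.normal(size=(60, 3)) + 1.0
        spec = WindowSpec(length_samples=12, stride_samples=2)
        starts, X, degen = batch_features(env, spec)
        assert not degen.any()
        for k, (start, w) in enumerate(sliding_windows(env, spec)):
            assert starts[k] == start
            np.testing.assert_allclose(X[k], window_features(w).flat,
                                       rtol=1e-12)


class TestBuildTrainingSet:
    def _signal(self, env, start, end, label, trimmed=False):
        return PreprocessedSignal(envelope=env, fs=200.0,
                                  activity_start=start, activity_end=end,
                                  source_length=env.shape[0],
                                  trimmed=trimmed, gesture_label=label)

    def test_window_count_inside_activity(self):
        rng = np.random.default_rng(4)
        env = np.abs(rng.normal(0.1, 0.05, size=(200, 8)))
        sig = self._signal(env, 40, 160, 2)  # activity length 120
        X, y = build_training_set([sig], WindowSpec(80, 1),
                                  include_rest=False)
        assert X.shape == (41, 696)
        assert (y == 2).all()

    def test_rest_windows_labeled_zero(self):
        rng = np.random.default_rng(5)
        env = np.abs(rng.normal(0.05, 0.02, size=(150, 8)))
        sig = self._signal(env, 0, 0, 0)  # pure rest
        X, y = build_training_set([sig], WindowSpec(80, 1))
        assert (y == 0).all()
        assert X.shape[1] == 696

    def test_no_windows_at_all_rejected(self):
        rng = np.random.default_rng(6)
        env = np.abs(rng.normal(0.05, 0.02, size=(30, 8)))
        sig = self._signal(env, 0, 0, 0)
        with pytest.raises(ValueError, match="no training windows"):
            build_training_set([sig], WindowSpec(80, 1))

    def test_gesture_with_empty_activity_rejected(self):
        env = np.abs(np.random.default_rng(7).normal(size=(100, 8))) * 0.01
        sig = self._signal(env, 0, 0, 3)
        with pytest.raises(ValueError, match="empty activity"):
            build_training_set([sig], WindowSpec(20, 1))

    def test_boundary_straddling_windows_excluded(self):
        """Windows overlapping the activity boundary appear under neither
        label."""
        rng = np.random.default_rng(9)
        env = np.abs(rng.normal(0.1, 0.05, size=(200, 2)))
        sig = self._signal(env, 100, 160, 1)
        spec = WindowSpec(20, 1)
        X, y = build_training_set([sig], spec)
        n_gesture = (y == 1).sum()
        n_rest = (y == 0).sum()
        assert n_gesture == 60 - 20 + 1
        assert n_rest == (100 - 20 + 1) + (40 - 20 + 1)


def test_feature_matrix_round_trips_through_text(tmp_path):
    rng = np.random.default_rng(10)
    env = np.abs(rng.normal(0.1, 0.05, size=(120, 8)))
    spec = WindowSpec(20, 1)
    from emgrt.features import load_features, save_features
    _, X, _ = batch_features(env, spec)
    y = rng.integers(0, 4, size=X.shape[0])
    path = tmp_path / "features.tsv"
    save_features(path, X, y, spec, fs=200.0)
    X2, y2, sidecar = load_features(path)
    np.testing.assert_allclose(X2, X, rtol=1e-12)
    np.testing.assert_array_equal(y2, y)
    assert sidecar["window_length_samples"] == 20
    assert sidecar["flattening"] == "channel-major"
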