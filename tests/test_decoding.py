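import numpy as np
import pytest

from cortexloop.decoding import (
    PushPullParams,
    TrainingBuffer,
    TuningModel,
    calibrate_push_pull,
    fit_tuning,
    linear_decoder,
    population_vector,
    push_pull,
    select_features,
    shuffle_null,
)


def uniform_direction_buffer(n_reps=4, n_dirs=8, noise=0.0, n_noise_features=0, seed=0):
    """Features with known tuning over uniformly distributed directions."""
    rng = np.random.default_rng(seed)
    angles = np.tile(2 * np.pi * np.arange(n_dirs) / n_dirs, n_reps)
    K = np.column_stack([np.cos(angles), np.sin(angles)])
    f_tuned = 1.0 + 2.0 * K[:, 0]  # b0=1, bx=2, by=0
    features = [f_tuned + noise * rng.standard_normal(len(angles))]
    for _ in range(n_noise_features):
        features.append(rng.standard_normal(len(angles)))
    return TrainingBuffer.from_arrays(np.column_stack(features), K)


class TestFitTuning:
    def test_noiseless_exact_recovery(self):
        model = fit_tuning(uniform_direction_buffer())
        assert model.b0[0] == pytest.approx(1.0)
        assert model.bx[0] == pytest.approx(2.0)
        assert model.by[0] == pytest.approx(0.0, abs=1e-12)
        assert model.r2[0] == pytest.approx(1.0)
        assert np.allclose(model.pd[0], [1.0, 0.0])

    def test_untuned_features_have_low_r2(self, rng):
        angles = rng.uniform(0, 2 * np.pi, 500)
        K = np.column_stack([np.cos(angles), np.sin(angles)])
        F = rng.standard_normal((500, 200))
        model = fit_tuning(TrainingBuffer.from_arrays(F, K))
        assert np.mean(model.r2 < 0.05) > 0.9

    def test_too_few_frames_rejected(self):
        buf = TrainingBuffer.from_arrays(np.zeros((5, 1)), np.zeros((5, 2)))
        with pytest.raises(ValueError, match="10"):
            fit_tuning(buf)

    def test_collinear_targets_rejected(self):
        K = np.tile([1.0, 0.0], (20, 1))
        buf = TrainingBuffer.from_arrays(np.random.default_rng(0).standard_normal((20, 3)), K)
        with pytest.raises(ValueError, match="collinear|rank"):
            fit_tuning(buf)


class TestShuffleNull:
    def test_fixed_seed_reproducible(self):
        buf = uniform_direction_buffer(noise=0.5, n_noise_features=5)
        a = shuffle_null(buf, n_iter=50, seed=3)
        b = shuffle_null(buf, n_iter=50, seed=3)
        assert a == b

    def test_tuned_feature_far_above_null(self):
        buf = uniform_direction_buffer(n_reps=8)
        model = fit_tuning(buf)
        null = shuffle_null(buf, n_iter=200, seed=0)
        assert model.r2[0] == pytest.approx(1.0)
        assert null["p95"] < 0.5

    def test_percentiles_ordered(self):
        buf = uniform_direction_buffer(noise=1.0, n_noise_features=10)
        null = shuffle_null(buf, n_iter=100, seed=1)
        assert null["p80"] <= null["p90"] <= null["p95"]

    def test_bad_iteration_count_rejected(self):
        with pytest.raises(ValueError):
            shuffle_null(uniform_direction_buffer(), n_iter=0)


class TestSelectFeatures:
    def test_threshold_zero_selects_all(self):
        model = fit_tuning(uniform_direction_buffer(n_noise_features=4, noise=0.1))
        selected = select_features(model, 0.0)
        assert selected.selected.size == model.n_features
        assert not selected.selection_empty

    def test_threshold_above_one_selects_none_with_flag(self):
        model = fit_tuning(uniform_direction_buffer())
        selected = select_features(model, 1.0 + 1e-9)
        assert selected.selected.size == 0
        assert selected.selection_empty

    def test_threshold_is_replaceable_live(self):
        model = select_features(fit_tuning(uniform_direction_buffer()), 0.9)
        relaxed = select_features(model, 0.0)
        assert relaxed.threshold == 0.0
        assert relaxed.selected.size >= model.selected.size


def simple_model(pds, b0=None):
    pds = np.asarray(pds, dtype=float)
    n = len(pds)
    b0 = np.zeros(n) if b0 is None else np.asarray(b0, dtype=float)
    return TuningModel(
        b0=b0,
        bx=pds[:, 0],
        by=pds[:, 1],
        r2=np.ones(n),
        pd=pds,
        selected=np.arange(n),
    )


class TestPopulationVector:
    def test_single_feature_along_pd(self):
        model = simple_model([[1.0, 0.0]])
        P = population_vector(model, [1.0], gain=1.0)
        assert np.allclose(P.velocity, [1.0, 0.0])

    def test_two_features_vector_sum(self):
        model = simple_model([[1.0, 0.0], [0.0, 1.0]])
        P = population_vector(model, [1.0, 1.0])
        assert np.allclose(P.velocity, [1.0, 1.0])

    def test_zero_excess_zero_output(self):
        model = simple_model([[1.0, 0.0], [0.0, 1.0]], b0=[0.3, -0.2])
        P = population_vector(model, [0.3, -0.2])
        assert np.allclose(P.velocity, 0.0)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            population_vector(simple_model([[1.0, 0.0]]), [1.0, 2.0])

    def test_equals_equivalent_linear_decoder(self, rng):
        """The population vector is a particular linear readout: W rows are
        gain-scaled PDs of selected features, w0 collects the intercepts."""
        buf = uniform_direction_buffer(noise=0.3, n_noise_features=6, n_reps=6)
        model = select_features(fit_tuning(buf), 0.2)
        assert model.selected.size >= 1
        W, w0 = model.as_linear(gain=1.7)
        d = rng.standard_normal(model.n_features)
        assert np.allclose(
            population_vector(model, d, gain=1.7).velocity,
            linear_decoder(W, w0, d).velocity,
        )


class TestLinearDecoder:
    def test_scalar_case(self):
        assert np.allclose(linear_decoder([[2.0]], [0.0], [3.0]).velocity, [6.0])

    def test_zero_weights_give_intercept(self):
        v = linear_decoder(np.zeros((2, 3)), [0.5, -0.5], [1.0, 2.0, 3.0])
        assert np.allclose(v.velocity, [0.5, -0.5])

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            linear_decoder(np.zeros((2, 3)), [0.0, 0.0], [1.0, 2.0])


class TestPushPull:
    def test_balanced_inputs_zero(self):
        assert push_pull(1.5, 1.5, PushPullParams(a=2.0, b=0.0)).velocity[0] == 0.0

    @pytest.mark.parametrize(
        "a,b,s1,s2,expected", [(1.0, 0.0, 2.0, 0.5, 1.5), (2.0, 1.0, 1.0, 0.0, 1.0)]
    )
    def test_arithmetic(self, a, b, s1, s2, expected):
        assert push_pull(s1, s2, PushPullParams(a=a, b=b)).velocity[0] == pytest.approx(
            expected
        )

    def test_nonpositive_gain_rejected(self):
        with pytest.raises(ValueError):
            PushPullParams(a=0.0)

    def test_calibration_hand_check(self):
        p = calibrate_push_pull([0.0, 2.0])
        assert p.a == pytest.approx(1 / np.sqrt(2))
        assert p.b == pytest.approx(np.sqrt(2) / 2)
        out = [push_pull(s, 0.0, p).velocity[0] for s in (0.0, 2.0)]
        assert np.mean(out) == pytest.approx(0.0, abs=1e-12)
        assert np.var(out, ddof=1) == pytest.approx(1.0)

    def test_calibration_of_standardized_input(self, rng):
        x = rng.standard_normal(5000)
        x = (x - x.mean()) / x.std(ddof=1)
        p = calibrate_push_pull(x)
        assert p.a == pytest.approx(1.0, abs=1e-6)
        assert p.b == pytest.approx(0.0, abs=1e-6)

    def test_constant_input_degenerate(self):
        with pytest.raises(ValueError):
            calibrate_push_pull(np.ones(10))
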