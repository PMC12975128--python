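"""Reconstruction engine: windowing, loss, gradient prep, optimizer,
ensembling, ablation, post-processing."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import stimrecon as sr
from stimrecon.reconstruct import (
    OptimizerState,
    optimizer_step,
    poisson_nll,
    prepare_gradient,
    window_starts,
)
from stimrecon.stimuli import GRAY


class TestWindowStarts:
    @pytest.mark.parametrize(
        "T,expected",
        [(32, [0]), (40, [0, 8]), (48, [0, 8, 16]), (36, [0, 4])],
    )
    def test_examples(self, T, expected):
        assert window_starts(T) == expected

    def test_long_video_flush_window(self):
        starts = window_starts(300)
        assert len(starts) == 35 and starts[-1] == 268

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            window_starts(31)

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(st.integers(4, 200), st.integers(1, 32), st.integers(1, 16))
    def test_full_coverage_no_duplicates(self, T, size, stride):
        if T < size or stride > size:
            return
        starts = window_starts(T, size, stride)
        assert len(set(starts)) == len(starts)
        covered = np.zeros(T, bool)
        for s in starts:
            covered[s : s + size] = True
        assert covered.all()


class TestPoissonNLL:
    def test_examples(self):
        assert poisson_nll([[0.0]], [[2.0]]) == pytest.approx(2.0)
        assert poisson_nll([[1.0]], [[1.0]]) == pytest.approx(1.0, abs=1e-7)
        assert poisson_nll([[3.0]], [[np.e]]) == pytest.approx(-0.28172, abs=1e-4)

    def test_negative_prediction_rejected(self):
        with pytest.raises(ValueError):
            poisson_nll([[1.0]], [[-0.5]])


class TestPrepareGradient:
    def test_frobenius_normalization(self):
        out = prepare_gradient(np.array([[[3.0, 4.0]]]), None)
        assert np.allclose(out, [[[0.6, 0.8]]])

    def test_mask_gating(self):
        g = np.ones((2, 3, 3))
        assert np.all(prepare_gradient(g, np.zeros((3, 3))) == 0)

    def test_no_clipping_below_unit(self):
        out = prepare_gradient(np.array([[[10.0, 0.1]]]), None)
        assert np.allclose(out, [[[0.99995, 0.0099995]]], atol=1e-6)

    def test_zero_gradient_returns_zeros(self):
        assert np.all(prepare_gradient(np.zeros((2, 2, 2)), None) == 0)

    def test_scale_invariance(self, rng):
        """Summed vs averaged window losses differ only by a positive scale,
        which normalization removes."""
        g = rng.normal(size=(4, 5, 5))
        a = prepare_gradient(g, None)
        b = prepare_gradient(1000.0 * g, None)
        assert np.allclose(a, b)


class TestOptimizerStep:
    def test_first_step_bias_correction(self):
        st_ = OptimizerState(m=np.zeros(1), lr=1000.0, warmup=10)
        st_, update = optimizer_step(st_, np.ones(1), epoch=1)
        assert st_.m[0] == pytest.approx(0.1)
        assert update[0] == pytest.approx(1000.0 / 10 * 1.0)  # warmup lr * m_hat

    def test_second_step(self):
        st_ = OptimizerState(m=np.zeros(1), lr=100.0, warmup=10)
        st_, _ = optimizer_step(st_, np.ones(1), epoch=1)
        st_, update = optimizer_step(st_, np.ones(1), epoch=2)
        assert st_.m[0] == pytest.approx(0.19)
        assert st_.m[0] / (1 - 0.9**2) == pytest.approx(1.0)
        assert update[0] == pytest.approx(100.0 * 2 / 10)

    def test_warmup_ramp_reaches_full_lr(self):
        st_ = OptimizerState(m=np.zeros(1), lr=50.0, warmup=10)
        for epoch in range(1, 13):
            st_, update = optimizer_step(st_, np.ones(1), epoch)
        assert update[0] == pytest.approx(50.0 * st_.m[0] / (1 - 0.9**st_.t))

    def test_zero_gradients_leave_video_unchanged(self):
        video = np.full((2, 2, 2), GRAY)
        st_ = OptimizerState(m=np.zeros_like(video), lr=1000.0, warmup=10)
        for epoch in range(1, 6):
            st_, update = optimizer_step(st_, np.zeros_like(video), epoch)
            video = np.clip(video - update, 0, 255)
        assert np.all(video == GRAY)


@pytest.fixture(scope="module")
def recovery_fixture():
    """Small noise-free recovery problem shared across engine tests."""
    model = sr.make_reference_population(
        150, (3, 15, 3, 15), 0, frame_shape=(18, 18)
    )
    x = sr.generate_gp_video(sr.GPStimulusSpec(6, 6, 18, 18, 2.0), 1)
    beh = sr.BehaviorTrace.zeros(x.n_frames)
    y = model.predict(x, beh)
    mask = np.zeros((18, 18))
    mask[3:15, 3:15] = 1.0
    return model, x, beh, y, mask


class TestReconstruct:
    def test_zero_epochs_gray_video(self, recovery_fixture):
        model, x, beh, y, mask = recovery_fixture
        res = sr.reconstruct(model, y, beh, epochs=0)
        assert np.all(res.video.frames == GRAY)
        assert res.loss_trace.size == 0

    def test_loss_decreases(self, recovery_fixture):
        model, x, beh, y, mask = recovery_fixture
        res = sr.reconstruct(model, y, beh, epochs=40)
        assert res.loss_trace[-1] < res.loss_trace[0]

    def test_checkpoints_descend_loss_and_hold_recovery(self, recovery_fixture):
        """The optimization target (mean window NLL) decreases through the
        checkpoint epochs while masked recovery stays high. Pixel correlation
        itself need not grow with epochs: it is amplitude-invariant, so the
        first masked gradient steps already act as a matched filter, and
        later epochs trade correlation for likelihood."""
        model, x, beh, y, mask = recovery_fixture
        res = sr.reconstruct(model, y, beh, epochs=150)
        trace = res.loss_trace
        assert trace[49] < trace[9] and trace[149] < trace[49]
        for epochs in (10, 50, 150):
            r = sr.reconstruct(model, y, beh, epochs=epochs)
            post = sr.postprocess(r.video, mask, reference=x)
            assert sr.video_correlation(x, post, mask) >= 0.8

    def test_bit_identical_reruns(self, recovery_fixture):
        model, x, beh, y, mask = recovery_fixture
        a = sr.reconstruct(model, y, beh, epochs=8, seed=5)
        b = sr.reconstruct(model, y, beh, epochs=8, seed=5)
        assert np.array_equal(a.video.frames, b.video.frames)
        assert np.array_equal(a.loss_trace, b.loss_trace)

    def test_training_mask_confines_updates(self, recovery_fixture):
        model, x, beh, y, mask = recovery_fixture
        res = sr.reconstruct(model, y, beh, training_mask=mask, epochs=10)
        outside = res.video.frames[:, mask == 0]
        assert np.all(outside == GRAY)

    def test_gradient_ensemble_mode_runs(self, recovery_fixture):
        from stimrecon.encoder import perturb_model

        model, x, beh, y, mask = recovery_fixture
        models = [perturb_model(model, s) for s in (1, 2)]
        res = sr.reconstruct(models, y, beh, epochs=5, ensemble_mode="average_gradients")
        assert res.video.frames.shape == x.frames.shape
        assert np.all(np.isfinite(res.loss_trace))

    def test_model_target_mismatch_rejected(self, recovery_fixture):
        model, x, beh, y, mask = recovery_fixture
        with pytest.raises(ValueError):
            sr.reconstruct(model, y.values[:10], beh, epochs=1)


class TestEnsembleAverage:
    def test_identity_and_midpoint(self):
        v = sr.Video(np.full((2, 2, 2), 40.0))
        assert np.all(sr.ensemble_average([v, v, v]).frames == 40.0)
        lo = sr.Video(np.zeros((1, 2, 2)))
        hi = sr.Video(np.full((1, 2, 2), 255.0))
        assert np.all(sr.ensemble_average([lo, hi]).frames == 127.5)

    def test_permutation_invariance(self, rng):
        vids = [sr.Video(rng.uniform(0, 255, (2, 3, 3))) for _ in range(4)]
        a = sr.ensemble_average(vids).frames
        b = sr.ensemble_average(vids[::-1]).frames
        assert np.allclose(a, b)


class TestAblate:
    def test_extremes(self, rng):
        y = rng.uniform(0, 3, (8, 10))
        assert np.array_equal(sr.ablate(y, 0.0, 1).values, y)
        assert np.all(sr.ablate(y, 1.0, 1).values == 0)

    def test_exact_row_count(self, rng):
        y = rng.uniform(1, 3, (8, 10))
        out = sr.ablate(y, 0.5, 2).values
        assert int((out.sum(axis=1) == 0).sum()) == 4

    def test_invalid_fraction(self):
        with pytest.raises(ValueError):
            sr.ablate(np.ones((2, 2)), 1.5, 0)


class TestPostprocess:
    def test_constant_video_masked(self):
        v = sr.Video(np.full((4, 6, 6), 80.0))
        mask = np.zeros((6, 6))
        mask[2:4, 2:4] = 1
        out = sr.postprocess(v, mask).frames
        assert np.allclose(out[:, 2:4, 2:4], 80.0)
        assert np.all(out[:, 0, 0] == 0)

    def test_luminance_contrast_matching(self, rng):
        v = sr.Video(rng.uniform(50, 200, (5, 8, 8)))
        ref = sr.Video(rng.uniform(0, 255, (5, 8, 8)))
        out = sr.postprocess(v, np.ones((8, 8)), reference=ref, smooth_sigma=0.0)
        assert abs(out.frames.mean() - ref.frames.mean()) <= 1e-6
        assert abs(out.frames.std() - ref.frames.std()) <= 1e-6

    def test_smoothing_preserves_mean(self, rng):
        v = sr.Video(rng.uniform(0, 255, (6, 10, 10)))
        out = sr.postprocess(v, np.ones((10, 10)))
        assert abs(out.frames.mean() - v.frames.mean()) < 1e-3

    def test_zero_sd_reference_rejected(self):
        v = sr.Video(np.random.default_rng(0).uniform(0, 255, (3, 4, 4)))
        ref = sr.Video(np.full((3, 4, 4), 10.0))
        with pytest.raises(ValueError):
            sr.postprocess(v, np.ones((4, 4)), reference=ref)
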