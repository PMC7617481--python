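"""Network dynamics, Dale constraint, loss, gradients and training."""

import numpy as np
import pytest

from lateralpred import netmodel as nm
from lateralpred.synthetic_data import MovieClip


def scalar_loop_forward(params, frames):
    """Independent naive recurrence: explicit scalar loops, no matmul."""
    n_h, n_in = params.W_in.shape
    w = params.w_rec_effective
    s = np.zeros(n_h)
    S, V = [], []
    for t in range(frames.shape[0]):
        u = frames[t].ravel()
        z = np.empty(n_h)
        for i in range(n_h):
            acc = params.b_rec[i]
            for j in range(n_in):
                acc += params.W_in[i, j] * u[j]
            for j in range(n_h):
                acc += w[i, j] * s[j]
            z[i] = acc
        s = np.maximum(z, 0.0)
        S.append(s.copy())
        v = np.empty(params.W_out.shape[0])
        for k in range(params.W_out.shape[0]):
            v[k] = params.b_out[k] + sum(params.W_out[k, j] * s[j]
                                         for j in range(n_h))
        V.append(v)
    return np.array(S), np.array(V)


class TestArchitecture:
    def test_default_config_printed_unit_counts(self):
        cfg = nm.NetworkConfig()
        assert cfg.n_input == 1296
        assert cfg.n_hidden == 2592
        assert cfg.n_excitatory == 2332
        assert cfg.n_inhibitory == 260
        params = nm.init_network(cfg)
        assert int((params.unit_sign > 0).sum()) == 2332
        assert int((params.unit_sign < 0).sum()) == 260
        assert params.W_in.shape == (2592, 1296)

    def test_same_seed_identical_init(self):
        cfg = nm.NetworkConfig(n_input=9, n_hidden=10, seed=5)
        a, b = nm.init_network(cfg), nm.init_network(cfg)
        np.testing.assert_array_equal(a.W_rec, b.W_rec)
        np.testing.assert_array_equal(a.W_in, b.W_in)

    def test_invalid_configs_rejected(self):
        with pytest.raises(ValueError):
            nm.NetworkConfig(frac_inhibitory=0.0)
        with pytest.raises(ValueError):
            nm.NetworkConfig(lambda_l1=-1)
        with pytest.raises(ValueError):
            nm.NetworkConfig(objective="nope")


class TestDaleConstraint:
    def test_sign_pattern(self):
        sign = np.array([1.0, -1.0])
        W = np.array([[-3.0, 2.0], [5.0, -7.0]])
        out = nm.apply_dale_constraint(W, sign)
        # column = presynaptic: excitatory col 0 -> +|w|, inhibitory col 1 -> -|w|
        np.testing.assert_array_equal(out, [[3.0, -2.0], [5.0, -7.0]])

    def test_zero_stays_zero_and_idempotent(self):
        sign = np.array([1.0, -1.0, 1.0])
        W = np.random.default_rng(0).standard_normal((3, 3))
        W[0, 0] = 0.0
        once = nm.apply_dale_constraint(W, sign)
        assert once[0, 0] == 0.0
        np.testing.assert_array_equal(once, nm.apply_dale_constraint(once, sign))

    def test_constraint_holds_after_training(self, small_corpus):
        train_clips, val_clips = small_corpus
        cfg = nm.NetworkConfig.desk_profile(n_epochs=2, batch_size=16, seed=1)
        params = nm.init_network(cfg)
        params, _ = nm.train(params, train_clips[:20], cfg)
        w = params.w_rec_effective
        exc = params.unit_sign > 0
        assert np.all(w[:, exc] >= 0)
        assert np.all(w[:, ~exc] <= 0)


class TestForward:
    def test_zero_input_zero_state(self, tiny_net):
        params, cfg = tiny_net
        p = params.copy()
        p.b_rec[...] = 0
        p.b_out[...] = 7.0
        state = nm.forward(p, np.zeros((4, 4)))
        np.testing.assert_array_equal(state.s, 0.0)
        np.testing.assert_array_equal(state.v_hat, 7.0)

    def test_memoryless_when_w_rec_zero(self, tiny_net):
        params, _ = tiny_net
        p = params.copy()
        p.W_rec[...] = 0
        frames = np.random.default_rng(0).standard_normal((6, 4))
        full = nm.forward(p, frames)
        for t in range(6):
            single = nm.forward(p, np.vstack([frames[t], frames[t]]))
            np.testing.assert_allclose(full.s[t], single.s[0], atol=1e-12)

    def test_matches_scalar_loop_oracle(self, tiny_net):
        params, _ = tiny_net
        frames = np.random.default_rng(1).standard_normal((6, 2, 2))
        state = nm.forward(params, MovieClip(frames))
        S, V = scalar_loop_forward(params, frames)
        assert np.abs(S - state.s).max() < 1e-10
        assert np.abs(V - state.v_hat).max() < 1e-10

    def test_hidden_activity_nonnegative_and_reproducible(self, tiny_net):
        params, _ = tiny_net
        frames = np.random.default_rng(2).standard_normal((20, 4))
        a = nm.forward(params, frames)
        b = nm.forward(params, frames)
        assert np.all(a.s >= 0)
        np.testing.assert_array_equal(a.s, b.s)

    def test_nan_input_rejected(self, tiny_net):
        params, _ = tiny_net
        bad = np.full((3, 4), np.nan)
        with pytest.raises(ValueError):
            nm.forward(params, bad)


class TestTargetsAndLoss:
    def test_offset_one_on_50_frames_gives_49_steps(self):
        clip = MovieClip(np.random.default_rng(0).standard_normal((50, 4, 4)))
        inp, tgt = nm.make_targets(clip, "prediction", 1)
        assert inp.n_frames == 49 and tgt.shape == (49, 16)
        np.testing.assert_array_equal(tgt[0], clip.flatten()[1])

    def test_offset_zero_identity_pairing(self):
        clip = MovieClip(np.random.default_rng(1).standard_normal((10, 4, 4)))
        inp, tgt = nm.make_targets(clip, "prediction", 0)
        np.testing.assert_array_equal(inp.flatten(), tgt)

    def test_offset_span_concatenates(self):
        clip = MovieClip(np.random.default_rng(2).standard_normal((10, 4, 4)))
        inp, tgt = nm.make_targets(clip, "prediction", (1, 3))
        assert tgt.shape == (7, 32)
        np.testing.assert_array_equal(tgt[0, :16], clip.flatten()[1])
        np.testing.assert_array_equal(tgt[0, 16:], clip.flatten()[3])

    def test_denoise_corruption_snr_3db(self):
        clip = MovieClip(np.random.default_rng(3).standard_normal((50, 16, 16)))
        inp, tgt = nm.make_targets(clip, "denoise", config=nm.NetworkConfig.desk_profile())
        np.testing.assert_array_equal(tgt, clip.flatten())
        snr = 10 * np.log10(clip.frames.var()
                            / (inp.frames - clip.frames).var())
        assert abs(snr - 3.0) < 0.3

    def test_excessive_offset_rejected(self):
        clip = MovieClip(np.zeros((5, 2, 2)))
        with pytest.raises(ValueError):
            nm.make_targets(clip, "prediction", 5)

    def test_loss_trivial_values(self, tiny_net):
        params, cfg = tiny_net
        p = params.copy()
        for name in ("W_in", "W_rec", "W_out", "b_rec", "b_out"):
            getattr(p, name)[...] = 0
        state = nm.NetworkState(s=np.zeros((3, 5)), v_hat=np.zeros((3, 4)))
        targets = np.zeros((3, 4))
        c = nm.NetworkConfig(n_input=4, n_hidden=5, frac_inhibitory=0.2,
                             lambda_l1=1.0)
        assert nm.loss(p, state, targets, c) == 0.0
        # perfect predictions, lambda=1, sum|W|=7 -> E=7
        p.W_in[0, 0] = 3.0
        p.W_rec[1, 1] = -4.0
        assert nm.loss(p, state, targets, c) == pytest.approx(7.0)
        # unit error in one pixel, lambda=0 -> E=1
        state2 = nm.NetworkState(s=np.zeros((1, 5)), v_hat=np.array([[1.0, 0, 0, 0]]))
        c0 = nm.NetworkConfig(n_input=4, n_hidden=5, frac_inhibitory=0.2,
                              lambda_l1=0.0)
        assert nm.loss(p, state2, np.zeros((1, 4)), c0) == pytest.approx(1.0)

    def test_loss_shape_mismatch_rejected(self, tiny_net):
        params, _ = tiny_net
        state = nm.NetworkState(s=np.zeros((3, 5)), v_hat=np.zeros((3, 4)))
        c = nm.NetworkConfig(n_input=4, n_hidden=5, frac_inhibitory=0.2)
        with pytest.raises(ValueError):
            nm.loss(params, state, np.zeros((3, 5)), c)


class TestGradients:
    def test_analytic_matches_finite_differences(self):
        """BPTT gradient vs central differences on a 3-unit network."""
        cfg = nm.NetworkConfig(n_input=4, n_hidden=3, frac_inhibitory=0.34,
                               lambda_l1=1e-3, lambda_act=1e-3,
                               objective="sparse_ae", seed=3)
        params = nm.init_network(cfg)
        rng = np.random.default_rng(0)
        U = rng.standard_normal((2, 5, 4))
        V = rng.standard_normal((2, 5, 4))
        _, grads = nm.loss_and_gradients(params, U, V, cfg)
        eps = 1e-6
        for key, g in grads.items():
            arr = getattr(params, key)
            it = np.nditer(arr, flags=["multi_index"])
            for _ in it:
                i = it.multi_index
                old = arr[i]
                arr[i] = old + eps
                lp, _ = nm.loss_and_gradients(params, U, V, cfg)
                arr[i] = old - eps
                lm, _ = nm.loss_and_gradients(params, U, V, cfg)
                arr[i] = old
                num = (lp - lm) / (2 * eps)
                assert abs(g[i] - num) / max(abs(num), 1e-6) < 1e-4, key


class TestTraining:
    def test_short_training_reduces_validation_mse(self, small_corpus):
        train_clips, val_clips = small_corpus
        cfg = nm.NetworkConfig.desk_profile(n_epochs=4, batch_size=16,
                                            learning_rate=3e-4, seed=2)
        params = nm.init_network(cfg)
        before = nm.evaluate_mse(params, val_clips, cfg)
        params, history = nm.train(params, train_clips, cfg, validation=val_clips)
        after = nm.evaluate_mse(params, val_clips, cfg)
        assert after < before
        assert history.val_mse.iloc[-1] < history.val_mse.iloc[0]

    def test_empty_corpus_rejected(self):
        cfg = nm.NetworkConfig.desk_profile()
        with pytest.raises(ValueError):
            nm.train(nm.init_network(cfg), [], cfg)

    def test_higher_lambda_shrinks_weights(self, small_corpus):
        train_clips, _ = small_corpus
        medians = []
        for lam in (1e-5, 1e-2):
            cfg = nm.NetworkConfig.desk_profile(n_epochs=3, batch_size=16,
                                                learning_rate=3e-4,
                                                lambda_l1=lam, seed=4)
            params = nm.init_network(cfg)
            params, _ = nm.train(params, train_clips[:30], cfg)
            medians.append(np.median(np.abs(params.W_rec)))
        assert medians[1] < medians[0]

    def test_persistence_baseline_value(self):
        frames = np.zeros((3, 1, 2))
        frames[1, 0, 0] = 1.0  # one pixel flips on then off
        clip = MovieClip(frames)
        # diffs: t0->t1 and t1->t2 each change one of two pixels
        assert nm.persistence_mse([clip]) == pytest.approx(0.5)


class TestSweep:
    def test_single_value_grid(self, small_corpus):
        train_clips, val_clips = small_corpus
        base = nm.NetworkConfig.desk_profile(n_epochs=1, batch_size=16, seed=0)
        table = nm.hyperparameter_sweep(train_clips[:10], val_clips,
                                        lambda_grid=[1e-5], base_config=base)
        assert len(table) == 1 and bool(table.selected.iloc[0])

    def test_selected_is_argmin(self, small_corpus):
        train_clips, val_clips = small_corpus
        base = nm.NetworkConfig.desk_profile(n_epochs=1, batch_size=16, seed=0)
        table = nm.hyperparameter_sweep(train_clips[:10], val_clips,
                                        lambda_grid=[1e-6, 1e-1],
                                        base_config=base)
        assert table.val_mse[table.selected].iloc[0] == table.val_mse.min()

    def test_requires_exactly_one_grid(self, small_corpus):
        train_clips, val_clips = small_corpus
        with pytest.raises(ValueError):
            nm.hyperparameter_sweep(train_clips, val_clips)


class TestCheckpointIO:
    def test_roundtrip(self, tmp_path, tiny_net):
        params, cfg = tiny_net
        path = tmp_path / "ckpt.h5"
        nm.save_checkpoint(path, params, cfg, epoch=3)
        loaded, lcfg, epoch = nm.load_checkpoint(path)
        assert epoch == 3
        assert lcfg.n_hidden == cfg.n_hidden
        np.testing.assert_array_equal(loaded.W_rec, params.W_rec)
        np.testing.assert_array_equal(loaded.unit_sign, params.unit_sign)
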