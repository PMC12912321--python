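import numpy as np
import pytest

from mcma.model import (CHECKPOINT_FORMAT, Adam, ModelConfig, build_model,
                        load_checkpoint, save_checkpoint)

SMALL = dict(channel_widths=(8, 16), depth=2, seed=11)


class TestConfig:
    def test_depth_width_mismatch(self):
        with pytest.raises(ValueError):
            ModelConfig(depth=3, channel_widths=(8, 16))

    def test_even_kernel_rejected(self):
        with pytest.raises(ValueError):
            ModelConfig(kernel_size=4)

    def test_seq_len_divisibility(self):
        with pytest.raises(ValueError):
            ModelConfig(depth=5, channel_widths=(4,) * 5, stride=3)

    def test_roundtrip_dict(self):
        cfg = ModelConfig(**SMALL)
        assert ModelConfig.from_dict(cfg.to_dict()) == cfg


class TestForward:
    def test_shape_contract(self):
        m = build_model(ModelConfig(**SMALL))
        x = np.random.default_rng(0).normal(size=(3, 12, 1024))
        y = m.forward(x)
        assert y.shape == (3, 12, 1024)
        assert np.all(np.isfinite(y))

    def test_single_window_shape(self):
        m = build_model(ModelConfig(**SMALL))
        y = m.forward(np.zeros((12, 1024)))
        assert y.shape == (12, 1024)

    @pytest.mark.parametrize("length", [512, 1024])
    def test_output_length_follows_input(self, length):
        m = build_model(ModelConfig(**SMALL))
        y = m.forward(np.zeros((1, 12, length)))
        assert y.shape == (1, 12, length)

    def test_bottleneck_length_is_len_over_stride_pow_depth(self):
        cfg = ModelConfig(channel_widths=(4, 4, 4, 4, 4), depth=5, seed=0)
        m = build_model(cfg)
        m.forward(np.zeros((1, 12, 1024)))
        assert m._skips_shapes[-1][1] == 1024 // 2 ** 5 == 32
        assert m._skips_shapes[-1][2] == 4

    def test_same_seed_same_outputs(self):
        cfg = ModelConfig(**SMALL)
        x = np.random.default_rng(1).normal(size=(2, 12, 1024))
        assert np.array_equal(build_model(cfg).forward(x),
                              build_model(cfg).forward(x))

    def test_forward_is_deterministic(self):
        m = build_model(ModelConfig(**SMALL))
        x = np.random.default_rng(2).normal(size=(2, 12, 1024))
        assert np.array_equal(m.forward(x), m.forward(x))

    def test_forward_batch_independent(self):
        # per-sample norms: a sample's output must not depend on batch mates
        m = build_model(ModelConfig(**SMALL))
        x = np.random.default_rng(3).normal(size=(4, 12, 1024)).astype(np.float32)
        full = m.forward(x)
        alone = m.forward(x[1:2])
        np.testing.assert_allclose(full[1], alone[0], atol=1e-5)

    def test_zero_input_gives_constant_per_channel(self):
        m = build_model(ModelConfig(**SMALL))
        y = m.forward(np.zeros((1, 12, 1024)))
        assert np.allclose(y.std(axis=2), 0.0, atol=1e-5)

    def test_wrong_channel_count_rejected(self):
        m = build_model(ModelConfig(**SMALL))
        with pytest.raises(ValueError):
            m.forward(np.zeros((1, 3, 1024)))
        with pytest.raises(ValueError):
            m.forward(np.zeros((1, 12, 1002)))

    def test_concat_skips_build_and_run(self):
        m = build_model(ModelConfig(skips="concat", **SMALL))
        y = m.forward(np.zeros((1, 12, 1024)))
        assert y.shape == (1, 12, 1024)

    def test_param_count_regression(self):
        assert build_model(ModelConfig()).num_params() == 4291564
        assert build_model(ModelConfig(
            channel_widths=(16, 32, 64, 128, 256), depth=5)).num_params() == 1075452


class TestGradients:
    def _loss_and_backward(self, m, x, tgt):
        pred = m.forward(x)
        err = pred - tgt
        m.backward(2.0 / err.size * err)
        return np.mean(err ** 2)

    def test_gradcheck_without_norms(self):
        # without norms there are no null parameter directions, so every
        # coordinate can be compared against central differences
        cfg = ModelConfig(kernel_size=3, stride=2, depth=2,
                          channel_widths=(3, 4), dtype="float64", seed=3,
                          norms=(False, False))
        m = build_model(cfg)
        rng = np.random.default_rng(5)
        x = rng.normal(size=(2, 12, 8))
        tgt = rng.normal(size=(2, 12, 8))
        self._loss_and_backward(m, x, tgt)
        worst = 0.0
        for p, g in m.parameters():
            for _ in range(3):
                idx = tuple(rng.integers(0, s) for s in p.shape)
                eps, old = 1e-6, p[idx]
                p[idx] = old + eps
                lp = np.mean((m.forward(x) - tgt) ** 2)
                p[idx] = old - eps
                lm = np.mean((m.forward(x) - tgt) ** 2)
                p[idx] = old
                num = (lp - lm) / (2 * eps)
                worst = max(worst, abs(num - g[idx]) /
                            max(1e-8, abs(num) + abs(g[idx])))
        assert worst < 1e-5

    def test_directional_derivative_with_norms(self):
        # full architecture incl. LN/IN: compare the directional derivative
        # along a random direction with the analytic gradient projection
        cfg = ModelConfig(kernel_size=3, stride=2, depth=2,
                          channel_widths=(3, 4), dtype="float64", seed=9)
        m = build_model(cfg)
        rng = np.random.default_rng(13)
        x = rng.normal(size=(2, 12, 8))
        tgt = rng.normal(size=(2, 12, 8))
        self._loss_and_backward(m, x, tgt)
        params = m.parameters()
        direction = [rng.normal(size=p.shape) for p, _ in params]
        analytic = sum(float(np.sum(g * d)) for (_, g), d in zip(params, direction))
        eps = 1e-6
        for sign in (+1, -1):
            for (p, _), d in zip(params, direction):
                p += sign * eps * d
            loss = float(np.mean((m.forward(x) - tgt) ** 2))
            if sign > 0:
                lp = loss
            else:
                lm = loss
            for (p, _), d in zip(params, direction):
                p -= sign * eps * d
        numeric = (lp - lm) / (2 * eps)
        assert abs(numeric - analytic) / max(1e-8, abs(numeric)) < 1e-6

    def test_adam_reduces_loss_on_one_batch(self):
        cfg = ModelConfig(kernel_size=3, stride=2, depth=2,
                          channel_widths=(6, 8), seed=2)
        m = build_model(cfg)
        rng = np.random.default_rng(4)
        x = rng.normal(size=(4, 12, 1024)).astype(np.float32)
        tgt = rng.normal(size=(4, 12, 1024)).astype(np.float32)
        opt = Adam(m.parameters(), lr=1e-3)
        losses = []
        for _ in range(60):
            losses.append(self._loss_and_backward(m, x, tgt))
            opt.step()
        assert losses[-1] < 0.7 * losses[0]


class TestCheckpoint:
    def test_save_load_forward_bitwise(self, tmp_path):
        m = build_model(ModelConfig(**SMALL))
        x = np.random.default_rng(8).normal(size=(1, 12, 1024))
        y0 = m.forward(x)
        p = save_checkpoint(m, tmp_path / "ck.zip",
                            history=[{"epoch": 0, "val_mse": 1.0}])
        ck = load_checkpoint(p)
        assert np.array_equal(ck.build().forward(x), y0)
        assert ck.history[0]["val_mse"] == 1.0
        assert ck.config == m.config

    def test_missing_file(self, tmp_path):
        with pytest.raises(FileNotFoundError):
            load_checkpoint(tmp_path / "nope.zip")

    def test_format_version_mismatch(self, tmp_path):
        import json
        import zipfile

        bad = tmp_path / "bad.zip"
        with zipfile.ZipFile(bad, "w") as zf:
            zf.writestr("meta.json", json.dumps({"format": "other-format-9"}))
        with pytest.raises(ValueError, match=CHECKPOINT_FORMAT):
            load_checkpoint(bad)
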