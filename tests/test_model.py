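import numpy as np
import pytest

from gaitstream import (
    FusionNet,
    FusionNetConfig,
    build_jp,
    build_rjdp,
    build_variant,
    cross_entropy,
    fuse,
)
from gaitstream import nn
from gaitstream.model import classify

from test_features import _tiny_skeleton
from conftest import make_sample


def brute_force_conv2d(x, W, b, stride, padding=(0, 0)):
    """Direct nested-loop convolution oracle on NHWC input.

    x: (H, W, C); W: (O, C, kh, kw); returns (Ho, Wo, O).
    """
    h, w, c = x.shape
    o, _, kh, kw = W.shape
    sh, sw = stride
    ph, pw = padding
    xp = np.zeros((h + 2 * ph, w + 2 * pw, c))
    xp[ph : ph + h, pw : pw + w] = x
    ho = (h + 2 * ph - kh) // sh + 1
    wo = (w + 2 * pw - kw) // sw + 1
    out = np.zeros((ho, wo, o))
    for a in range(ho):
        for bcol in range(wo):
            for oc in range(o):
                acc = b[oc]
                for dc in range(c):
                    for i in range(kh):
                        for j in range(kw):
                            acc += (
                                W[oc, dc, i, j]
                                * xp[a * sh + i, bcol * sw + j, dc]
                            )
                out[a, bcol, oc] = acc
    return out


class TestShapeChain:
    def test_default_shapes_end_to_end(self, normalized_sample):
        model = FusionNet(FusionNetConfig(), seed=0)
        S = build_jp(normalized_sample).S
        Sp = build_rjdp(normalized_sample).S_prime
        assert S.shape == (100, 20, 3)
        assert Sp.shape == (100, 380, 3)
        f_jp = model.stream_jp(S)
        f_rjdp = model.stream_rjdp(Sp)
        assert f_jp.shape == (98, 20, 3)
        assert f_rjdp.shape == (98, 20, 3)
        f = fuse(f_jp, f_rjdp)
        assert f.shape == (98, 20, 6)
        p = classify(f, model)
        assert p.shape == (4,)

    def test_stream2_width_is_j(self):
        # ((J(J-1)) - (J-1)) / (J-1) + 1 == J
        for J in (3, 5, 20):
            assert (J * (J - 1) - (J - 1)) // (J - 1) + 1 == J

    def test_t_too_small_rejected(self):
        model = FusionNet(FusionNetConfig(), seed=0)
        with pytest.raises(ValueError, match="too small"):
            model.stream_jp(np.zeros((2, 20, 3)))

    def test_wrong_joint_count_rejected(self):
        model = FusionNet(FusionNetConfig(), seed=0)
        with pytest.raises(ValueError, match="joints"):
            model.stream_jp(np.zeros((10, 19, 3)))
        with pytest.raises(ValueError, match="380"):
            model.stream_rjdp(np.zeros((10, 100, 3)))


class TestConvOracle:
    @pytest.mark.parametrize("kernel,stride,padding,h,w", [
        ((3, 1), (1, 1), (0, 0), 6, 4),
        ((3, 2), (1, 2), (0, 0), 5, 6),
        ((3, 1), (1, 1), (1, 0), 4, 3),
        ((3, 19), (1, 19), (0, 0), 7, 380),
    ])
    def test_conv_matches_brute_force(self, rng, kernel, stride, padding, h, w):
        c_in, c_out = 3, 2
        conv = nn.Conv2d(c_in, c_out, kernel=kernel, stride=stride,
                         padding=padding, rng=rng)
        x = rng.standard_normal((h, w, c_in)).astype(np.float32)
        got = conv.forward(x[None])[0]
        want = brute_force_conv2d(
            x.astype(float), conv.W.astype(float), conv.b.astype(float),
            stride, padding,
        )
        np.testing.assert_allclose(got, want, atol=1e-5)

    def test_conv_gradients_match_finite_differences(self, rng):
        conv = nn.Conv2d(2, 3, kernel=(3, 2), stride=(1, 2), rng=rng)
        x = rng.standard_normal((1, 5, 4, 2)).astype(np.float64)
        conv.W = conv.W.astype(np.float64)
        conv.b = conv.b.astype(np.float64)
        conv.gW = np.zeros_like(conv.W)
        conv.gb = np.zeros_like(conv.b)
        g = rng.standard_normal(conv.forward(x).shape)
        conv.zero_grad()
        gx = conv.backward(g)
        eps = 1e-6

        def loss(x_, W_, b_):
            W0, b0 = conv.W, conv.b
            conv.W, conv.b = W_, b_
            val = float((conv.forward(x_) * g).sum())
            conv.W, conv.b = W0, b0
            return val

        for idx in [(0, 1, 2, 0), (0, 4, 3, 1)]:
            xp = x.copy(); xp[idx] += eps
            xm = x.copy(); xm[idx] -= eps
            num = (loss(xp, conv.W, conv.b) - loss(xm, conv.W, conv.b)) / (2 * eps)
            assert gx[idx] == pytest.approx(num, rel=1e-4)
        for idx in [(0, 0, 0, 0), (2, 1, 2, 1)]:
            Wp = conv.W.copy(); Wp[idx] += eps
            Wm = conv.W.copy(); Wm[idx] -= eps
            num = (loss(x, Wp, conv.b) - loss(x, Wm, conv.b)) / (2 * eps)
            assert conv.gW[idx] == pytest.approx(num, rel=1e-4)

    def test_zero_weights_zero_output(self, rng):
        conv = nn.Conv2d(3, 3, kernel=(3, 1), rng=rng)
        conv.W[...] = 0.0
        conv.b[...] = 0.0
        out = conv.forward(rng.standard_normal((2, 6, 4, 3)).astype(np.float32))
        assert np.all(out == 0)

    def test_identity_tap_extracts_x_coordinate(self, rng):
        # single filter: center temporal tap 1 on channel x, zero elsewhere
        conv = nn.Conv2d(3, 1, kernel=(3, 1), rng=rng)
        conv.W[...] = 0.0
        conv.W[0, 0, 1, 0] = 1.0
        conv.b[...] = 0.0
        x = rng.standard_normal((4, 2, 3)).astype(np.float32)
        out = conv.forward(x[None])[0]
        np.testing.assert_allclose(out[:, :, 0], x[1:3, :, 0], atol=1e-6)

    def test_rjdp_block_toy_j3(self, rng):
        # J=3: width 6, kernel 2, stride 2 -> output width 3
        cfg = FusionNetConfig(n_joints=3, t_frames=5)
        model = FusionNet(cfg, seed=1)
        sp = rng.standard_normal((5, 6, 3)).astype(np.float32)
        out = model.stream_rjdp(sp)
        assert out.shape == (3, 3, 3)
        want = brute_force_conv2d(
            sp.astype(float),
            model.conv_rjdp.W.astype(float),
            model.conv_rjdp.b.astype(float),
            (1, 2),
        )
        np.testing.assert_allclose(out, want, atol=1e-5)


class TestFuse:
    def test_channel_concat_order(self, rng):
        a = rng.standard_normal((98, 20, 3))
        b = rng.standard_normal((98, 20, 3))
        f = fuse(a, b)
        assert f.shape == (98, 20, 6)
        np.testing.assert_array_equal(f[..., :3], a)
        np.testing.assert_array_equal(f[..., 3:], b)
        assert not np.array_equal(fuse(a, b), fuse(b, a))

    def test_zero_second_stream(self, rng):
        a = rng.standard_normal((10, 4, 3))
        f = fuse(a, np.zeros_like(a))
        assert np.all(f[..., 3:] == 0)

    def test_shape_mismatch_rejected(self, rng):
        with pytest.raises(ValueError, match="disagree"):
            fuse(rng.standard_normal((9, 20, 3)), rng.standard_normal((98, 20, 3)))


class TestClassify:
    def test_probability_simplex(self, rng):
        model = FusionNet(FusionNetConfig(), seed=3)
        f = rng.standard_normal((98, 20, 6))
        p = classify(f, model)
        assert np.all(p >= 0) and np.all(p <= 1)
        assert p.sum() == pytest.approx(1.0, abs=1e-6)

    def test_zero_final_layer_uniform(self, rng):
        model = FusionNet(FusionNetConfig(), seed=3)
        fc = model.head.layers[-1]
        fc.W[...] = 0.0
        fc.b[...] = 0.0
        p = classify(rng.standard_normal((98, 20, 6)), model)
        np.testing.assert_allclose(p, 0.25, atol=1e-7)

    def test_scaling_logits_preserves_argmax(self, rng):
        logits = rng.standard_normal((6, 4))
        assert np.array_equal(
            nn.softmax(logits).argmax(axis=1), nn.softmax(2 * logits).argmax(axis=1)
        )


class TestCrossEntropy:
    def test_perfect_prediction(self):
        assert cross_entropy([0.0, 1.0, 0.0, 0.0], [0, 1, 0, 0]) == pytest.approx(0.0, abs=1e-9)

    def test_uniform_log4(self):
        p = [0.25] * 4
        assert cross_entropy(p, [1, 0, 0, 0]) == pytest.approx(np.log(4), abs=1e-9)

    def test_half_log2(self):
        assert cross_entropy([0.5, 0.5, 0, 0], [1, 0, 0, 0]) == pytest.approx(np.log(2), abs=1e-9)

    def test_matches_neg_log_p_true_on_random_simplex(self, rng):
        for _ in range(50):
            p = rng.dirichlet(np.ones(4))
            k = rng.integers(4)
            y = np.eye(4)[k]
            assert cross_entropy(p, y) == pytest.approx(-np.log(p[k]), abs=1e-9)

    def test_zero_probability_clamped(self):
        val = cross_entropy([0.0, 1.0], [1, 0])
        assert val == pytest.approx(-np.log(1e-12))


class TestVariants:
    @pytest.mark.parametrize("name", ["full", "no_cnn", "sin_cnn", "no_maxp"])
    def test_interface_contract(self, rng, name):
        cfg = FusionNetConfig(t_frames=20)
        model = build_variant(name, cfg, seed=0)
        S = rng.standard_normal((2, 20, 20, 3))
        Sp = rng.standard_normal((2, 20, 380, 3))
        p = model.predict_proba(S, Sp)
        assert p.shape == (2, 4)
        np.testing.assert_allclose(p.sum(axis=1), 1.0, atol=1e-6)

    def test_full_has_more_params_than_sin_cnn(self):
        cfg = FusionNetConfig(t_frames=20)
        assert build_variant("full", cfg).n_params > build_variant("sin_cnn", cfg).n_params

    def test_no_cnn_head_has_no_conv_params(self):
        model = build_variant("no_cnn", FusionNetConfig(t_frames=20))
        assert not any(isinstance(l, nn.Conv2d) for l in model.head.layers)

    def test_unknown_variant_rejected(self):
        with pytest.raises(ValueError, match="no_maxp"):
            build_variant("resnet")


class TestEquivariance:
    def test_joint_permutation_permutes_stream_outputs(self, rng):
        """Permuting S's joints and S' 's first-joint blocks consistently
        permutes the spatial axis of both stream outputs."""
        J, T = 5, 6
        cfg = FusionNetConfig(n_joints=J, t_frames=T)
        model = FusionNet(cfg, seed=2)
        sk = _tiny_skeleton(J)
        pos = rng.standard_normal((T, J, 3))
        sample = make_sample(pos, skeleton=sk)
        perm = rng.permutation(J)

        from gaitstream import build_rjdp as _rjdp
        from gaitstream.features import pair_index

        f_jp = model.stream_jp(pos.astype(np.float32))
        f_jp_perm = model.stream_jp(pos[:, perm].astype(np.float32))
        np.testing.assert_allclose(f_jp_perm, f_jp[:, perm], atol=1e-6)

        sp = _rjdp(sample).S_prime
        # permute S' block-wise: block k of the permuted tensor is the
        # original block of joint perm[k] (within-block order preserved)
        sp_blocks = sp.reshape(T, J, J - 1, 3)
        sp_perm = sp_blocks[:, perm].reshape(T, J * (J - 1), 3)
        f2 = model.stream_rjdp(sp.astype(np.float32))
        f2_perm = model.stream_rjdp(sp_perm.astype(np.float32))
        np.testing.assert_allclose(f2_perm, f2[:, perm], atol=1e-5)


class TestCheckpoint:
    def test_save_load_round_trip(self, tmp_path, rng):
        cfg = FusionNetConfig(t_frames=20)
        model = FusionNet(cfg, seed=9)
        S = rng.standard_normal((2, 20, 20, 3))
        Sp = rng.standard_normal((2, 20, 380, 3))
        before = model.predict_proba(S, Sp)
        model.save(tmp_path / "ckpt")
        loaded = FusionNet.load(tmp_path / "ckpt")
        after = loaded.predict_proba(S, Sp)
        np.testing.assert_allclose(after, before, atol=0)
        assert loaded.config == model.config
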