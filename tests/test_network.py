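import numpy as np
import pytest

from restlu import nn
from restlu import network as net
from restlu.exceptions import SpecError


def zero_residual_transforms(model):
    """Zero the final conv of every residual unit so f_i(x) == 0."""
    for enc in model.encoders:
        for stage in enc.stages:
            if isinstance(stage, net.ResidualUnit):
                stage.conv2.W[...] = 0.0
                stage.conv2.b[...] = 0.0


class TestArchSpec:
    def test_grid_not_divisible_by_16(self):
        with pytest.raises(SpecError):
            net.ArchSpec(grid=(250, 250))

    def test_channel_schedule_must_increase(self):
        with pytest.raises(SpecError):
            net.ArchSpec(encoder_channels=(16, 16, 32, 64, 128))

    def test_five_blocks_required(self):
        with pytest.raises(SpecError):
            net.ArchSpec(encoder_channels=(16, 32, 64, 128))

    def test_bottleneck_is_grid_over_16(self):
        assert net.ArchSpec(grid=(256, 256)).bottleneck_grid == (16, 16)


class TestBuild:
    def test_same_seed_bitwise_identical(self, tiny_spec):
        a = net.build_network(tiny_spec, 7).model.parameters()
        b = net.build_network(tiny_spec, 7).model.parameters()
        assert a.keys() == b.keys()
        for k in a:
            np.testing.assert_array_equal(a[k], b[k])

    def test_variants_share_output_shapes(self, rng, tiny_spec):
        x = rng.normal(size=(2, 3, 32, 32)).astype(np.float32)
        outs = {}
        for variant in ("unet", "restlu"):
            spec = net.ArchSpec(variant=variant,
                                encoder_channels=tiny_spec.encoder_channels,
                                grid=tiny_spec.grid)
            st = net.build_network(spec, 0)
            outs[variant] = net.forward(st, x)
            assert st.model.bottleneck.shape == (2, 12, 2, 2)
        assert outs["unet"].shape == outs["restlu"].shape == (2, 2, 32, 32)

    def test_forward_deterministic_in_inference(self, rng, tiny_spec):
        st = net.build_network(tiny_spec, 3)
        x = rng.normal(size=(2, 3, 32, 32)).astype(np.float32)
        np.testing.assert_array_equal(net.forward(st, x), net.forward(st, x))

    def test_grid_mismatch_rejected(self, rng, tiny_spec):
        st = net.build_network(tiny_spec, 0)
        with pytest.raises(SpecError):
            net.forward(st, rng.normal(size=(1, 3, 16, 16)).astype(np.float32))


class TestResidualUnit:
    def test_zero_transform_is_identity(self, rng):
        unit = net.ResidualUnit(6, 6, np.random.default_rng(0), "ru")
        unit.conv2.W[...] = 0.0
        unit.conv2.b[...] = 0.0
        x = rng.normal(size=(2, 6, 8, 8)).astype(np.float32)
        np.testing.assert_array_equal(net.residual_unit(x, unit), x)

    def test_zero_transform_with_projection(self, rng):
        unit = net.ResidualUnit(4, 6, np.random.default_rng(0), "ru")
        unit.conv2.W[...] = 0.0
        unit.conv2.b[...] = 0.0
        x = rng.normal(size=(2, 4, 8, 8)).astype(np.float32)
        out = net.residual_unit(x, unit)
        np.testing.assert_allclose(out, unit.proj.forward(x), atol=1e-6)

    def test_transform_matches_stepwise_composition(self, rng):
        # recompute f_i(x) = W . relu(B(W' . relu(B(x)))) step by step
        unit = net.ResidualUnit(5, 5, np.random.default_rng(1), "ru")
        x = rng.normal(size=(2, 5, 8, 8)).astype(np.float32)
        h = unit.bn1.forward(x)
        h = np.maximum(h, 0)
        h = unit.conv1.forward(h)
        h = unit.bn2.forward(h)
        h = np.maximum(h, 0)
        f = unit.conv2.forward(h)
        np.testing.assert_allclose(net.residual_unit(x, unit) - x, f,
                                   atol=1e-5)

    def test_zeroed_restlu_equals_shortcut_only_network(self, rng, tiny_spec):
        """With every residual transform zeroed, the ResTLU forward reduces
        to the strictly shallower network where each unit is just its
        shortcut projection."""
        st = net.build_network(tiny_spec, 5)
        zero_residual_transforms(st.model)
        x = rng.normal(size=(1, 3, 32, 32)).astype(np.float32)
        got = net.forward(st, x)

        m = st.model
        h = x
        skips = []
        for i in range(4):
            enc = m.encoders[i]
            h = enc.stages[0].shortcut(h)          # unit collapses to shortcut
            h = enc.stages[1].forward(h)
            h = enc.stages[2].forward(h)
            skips.append(h)
            h = m.pools[i].forward(h)
        enc = m.encoders[4]
        h = enc.stages[0].shortcut(h)
        h = enc.stages[1].forward(h)
        h = enc.stages[2].forward(h)
        for i in range(4):
            h = m.urelus[i].forward(m.tconvs[i].forward(h))
            h = np.concatenate([h, skips[3 - i]], axis=1)
        expected = m.head.forward(h)
        np.testing.assert_allclose(got, expected, atol=1e-5)


class TestLoss:
    def test_single_pixel_ln2(self):
        assert net.bce_loss(np.array([[0.5]]), np.array([[1.0]])) == \
            pytest.approx(np.log(2), rel=1e-9)

    def test_two_pixel_hand_evaluation(self):
        loss = net.bce_loss(np.array([0.9, 0.2]), np.array([1.0, 0.0]))
        assert loss == pytest.approx((-np.log(0.9) - np.log(0.8)) / 2,
                                     rel=1e-9)
        assert loss == pytest.approx(0.164252, abs=1e-6)

    def test_perfect_confident_prediction(self):
        y = np.array([1.0, 0.0, 1.0])
        assert net.bce_loss(y, y) <= 2e-7

    def test_shape_mismatch(self):
        with pytest.raises(SpecError):
            net.bce_loss(np.zeros((2, 2)), np.zeros(3))

    def test_gradient_matches_numeric(self):
        # 4x4 toy, float64 central differences vs analytic dL/dp
        rng = np.random.default_rng(0)
        p = rng.uniform(0.05, 0.95, (4, 4))
        y = (rng.random((4, 4)) > 0.5).astype(float)
        g = net.bce_loss_grad(p, y)
        eps = 1e-7
        for idx in np.ndindex(4, 4):
            pp = p.copy()
            pp[idx] += eps
            up = net.bce_loss(pp, y)
            pp[idx] -= 2 * eps
            dn = net.bce_loss(pp, y)
            num = (up - dn) / (2 * eps)
            assert num == pytest.approx(g[idx], rel=1e-4)

    def test_score_gradient_matches_numeric(self):
        rng = np.random.default_rng(1)
        s = rng.normal(size=(1, 2, 4, 4)).astype(np.float64)
        y = (rng.random((1, 4, 4)) > 0.5).astype(float)
        g = net.softmax_bce_score_grad(s, y)
        eps = 1e-6
        for c in range(2):
            for idx in np.ndindex(4, 4):
                sp = s.copy()
                sp[0, c][idx] += eps
                up = net.bce_loss(net.softmax_fg(sp), y)
                sp[0, c][idx] -= 2 * eps
                dn = net.bce_loss(net.softmax_fg(sp), y)
                assert (up - dn) / (2 * eps) == pytest.approx(
                    g[0, c][idx], rel=1e-3, abs=1e-9)


class TestDecode:
    def test_uniform_foreground_wins(self):
        scores = np.zeros((1, 2, 4, 4), dtype=np.float32)
        scores[:, 1] = 1.0
        np.testing.assert_array_equal(net.decode_mask(scores),
                                      np.ones((1, 4, 4), dtype=np.uint8))

    def test_exact_tie_goes_to_background(self):
        scores = np.full((1, 2, 4, 4), 0.3, dtype=np.float32)
        np.testing.assert_array_equal(net.decode_mask(scores),
                                      np.zeros((1, 4, 4), dtype=np.uint8))

    def test_matches_bruteforce_argmax(self, rng):
        scores = rng.normal(size=(3, 2, 6, 6)).astype(np.float32)
        got = net.decode_mask(scores)
        for b in range(3):
            for i in range(6):
                for j in range(6):
                    expect = 1 if scores[b, 1, i, j] > scores[b, 0, i, j] else 0
                    assert got[b, i, j] == expect

    def test_nonfinite_rejected(self):
        scores = np.zeros((1, 2, 4, 4))
        scores[0, 0, 0, 0] = np.nan
        with pytest.raises(FloatingPointError):
            net.decode_mask(scores)


class TestOptimization:
    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
    def test_one_adam_step_decreases_batch_loss(self, seed):
        spec = net.ArchSpec(variant="restlu",
                            encoder_channels=(4, 6, 8, 10, 12), grid=(16, 16))
        st = net.build_network(spec, seed)
        m = st.model
        rng = np.random.default_rng(100 + seed)
        x = rng.normal(size=(4, 3, 16, 16)).astype(np.float32)
        y = (rng.random((4, 16, 16)) > 0.5).astype(np.float32)
        opt = nn.Adam(lr=1e-4)
        s = m.forward(x, train=True)
        before = net.bce_loss(net.softmax_fg(s), y)
        m.zero_grad()
        m.backward(net.softmax_bce_score_grad(s, y))
        opt.step(m.parameters(), m.gradients())
        after = net.bce_loss(net.softmax_fg(m.forward(x, train=True)), y)
        assert after < before


class TestCheckpoint:
    def test_bit_exact_roundtrip(self, tmp_path, tiny_spec, rng):
        st = net.build_network(tiny_spec, 9)
        # dirty the running stats and attach optimizer state
        x = rng.normal(size=(2, 3, 32, 32)).astype(np.float32)
        st.model.forward(x, train=True)
        st.epoch = 3
        st.optimizer_state = {"t": 5,
                              "m": {k: v * 0.1 for k, v in
                                    st.model.parameters().items()},
                              "v": {k: np.abs(v) for k, v in
                                    st.model.parameters().items()}}
        p = tmp_path / "ckpt.npz"
        net.save_checkpoint(st, p)
        back = net.load_checkpoint(p)
        assert back.epoch == 3 and back.rng_seed == 9
        assert back.spec == tiny_spec
        for k, v in st.model.parameters().items():
            np.testing.assert_array_equal(back.model.parameters()[k], v)
        for k, v in st.model.buffers().items():
            np.testing.assert_array_equal(back.model.buffers()[k], v)
        assert back.optimizer_state["t"] == 5
        np.testing.assert_array_equal(net.forward(back, x), net.forward(st, x))
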