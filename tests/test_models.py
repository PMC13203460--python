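"""Architecture building blocks against hand-computed oracles."""

import numpy as np
import pytest

from ovimorph.nn import Tensor
from ovimorph.models import (
    AttentionFusionNet,
    BaselineConcatNet,
    CBAM,
    TabularEncoder,
    TokenFusionNet,
    build_net,
    encode_tabular_raw,
    forward_multitarget,
    patchify,
    scaled_dot_attention,
)


@pytest.fixture
def rng():
    return np.random.default_rng(12)


class TestTabularEncoding:
    def test_raw_encoding(self):
        v = encode_tabular_raw(3.0, "medium")
        assert np.allclose(v, [0.5, 0.0, 1.0, 0.0])

    def test_unknown_category_rejected(self):
        with pytest.raises(ValueError):
            encode_tabular_raw(3.0, "huge")

    def test_mlp_output_width(self, rng):
        enc = TabularEncoder((16, 32, 16), rng)
        out = enc(Tensor(encode_tabular_raw(2.5, "small")[None]))
        assert out.shape == (1, 16)

    def test_identity_single_layer_reproduces_input(self, rng):
        enc = TabularEncoder((4,), rng)
        layer = enc.mlp.net.layers[0]
        layer.weight.data[...] = np.eye(4)
        layer.bias.data[...] = 0.0
        raw = encode_tabular_raw(1.0, "small")  # non-negative, ReLU transparent
        out = enc(Tensor(raw[None]))
        assert np.allclose(out.data[0], raw)

    def test_equal_inputs_equal_encodings(self, rng):
        enc = TabularEncoder((8, 8), rng)
        a = enc(Tensor(encode_tabular_raw(3.5, "large")[None])).data
        b = enc(Tensor(encode_tabular_raw(3.5, "large")[None])).data
        assert np.array_equal(a, b)


class TestCBAM:
    def test_saturated_gates_give_identity(self, rng):
        block = CBAM(4, rng)
        block.fc1.weight.data[...] = 0
        block.fc2.weight.data[...] = 0
        block.fc1.bias.data[...] = 0
        block.fc2.bias.data[...] = 50.0  # sigmoid(100) ~ 1 (two branches sum)
        block.spatial_conv.weight.data[...] = 0
        block.spatial_conv.bias.data[...] = 100.0
        x = rng.normal(size=(2, 4, 5, 5))
        out = block(Tensor(x)).data
        assert np.allclose(out, x, atol=1e-10)

    def test_output_never_amplifies(self, rng):
        block = CBAM(6, rng)
        x = rng.normal(size=(3, 6, 4, 4))
        out = block(Tensor(x)).data
        assert np.all(np.abs(out) <= np.abs(x) + 1e-12)
        assert out.shape == x.shape

    def test_spatially_constant_input_gives_constant_spatial_gate(self, rng):
        block = CBAM(3, rng)
        x = np.broadcast_to(
            rng.normal(size=(1, 3, 1, 1)), (1, 3, 6, 6)
        ).copy()
        out = block(Tensor(x)).data
        # constant input, constant gates -> spatially constant output
        assert np.allclose(out, out[:, :, :1, :1], atol=1e-12)


class TestCrossModalAttention:
    def test_single_token_gets_weight_one(self):
        q = Tensor(np.array([[[1.0, 2.0]]]))
        kv = Tensor(np.array([[[0.3, -0.5]]]))
        _, w = scaled_dot_attention(q, kv, kv)
        assert np.allclose(w, [[1.0]])

    def test_identical_tokens_get_uniform_weights(self):
        q = Tensor(np.ones((1, 1, 3)))
        kv = Tensor(np.tile([[0.2, 0.4, -0.1]], (5, 1))[None])
        out, w = scaled_dot_attention(q, kv, kv)
        assert np.allclose(w, 1.0 / 5)
        assert np.allclose(out.data[0], [0.2, 0.4, -0.1])

    def test_two_token_weights_match_hand_softmax(self):
        q = np.array([[[1.0, 0.0]]])
        k = np.array([[[2.0, 0.0], [0.0, 2.0]]])
        v = np.array([[[1.0, 0.0], [0.0, 1.0]]])
        scores = np.array([2.0, 0.0]) / np.sqrt(2.0)
        expected = np.exp(scores) / np.exp(scores).sum()
        out, w = scaled_dot_attention(Tensor(q), Tensor(k), Tensor(v))
        assert np.allclose(w[0], expected)
        assert np.allclose(out.data[0], expected)  # values are the basis vectors

    def test_weights_positive_and_normalized(self, rng):
        q = Tensor(rng.normal(size=(4, 1, 8)))
        kv = Tensor(rng.normal(size=(4, 10, 8)))
        _, w = scaled_dot_attention(q, kv, kv)
        assert np.all(w > 0)
        assert np.allclose(w.sum(axis=1), 1.0)

    def test_empty_token_set_rejected(self):
        q = Tensor(np.ones((1, 1, 2)))
        kv = Tensor(np.ones((1, 0, 2)))
        with pytest.raises(ValueError):
            scaled_dot_attention(q, kv, kv)


class TestPatchify:
    @pytest.mark.parametrize(
        "size,patch,expected", [(224, 16, 196), (64, 8, 64), (32, 32, 1)]
    )
    def test_patch_counts(self, size, patch, expected, rng):
        img = Tensor(rng.normal(size=(1, 3, size, size)))
        assert patchify(img, patch).shape == (1, expected, 3 * patch * patch)

    def test_non_divisible_rejected(self, rng):
        with pytest.raises(ValueError):
            patchify(Tensor(rng.normal(size=(1, 3, 30, 30))), 8)

    def test_patch_content_row_major(self, rng):
        img = rng.normal(size=(1, 1, 4, 4))
        x = np.concatenate([img, img, img], axis=1)
        patches = patchify(Tensor(x), 2).data
        # first patch is the top-left 2x2 block of each channel
        expected = np.concatenate([img[0, 0, :2, :2].ravel()] * 3)
        assert np.allclose(patches[0, 0], expected)


class TestForward:
    def _inputs(self, rng, n=2, size=32):
        return (rng.normal(size=(n, 3, size, size)),
                rng.normal(size=(n, 3, size, size)),
                rng.normal(size=(n, 4)))

    @pytest.mark.parametrize("family", ["baseline_concat", "attention_fusion", "token_fusion"])
    def test_four_finite_outputs_and_determinism(self, family, rng):
        kwargs = {"backbone": (4, 8)} if family != "token_fusion" else {
            "image_size": 32, "patch_size": 8, "embed_dim": 16, "n_heads": 2, "n_layers": 1}
        net = build_net(family, np.random.default_rng(3), **kwargs)
        d, l, t = self._inputs(rng)
        out1 = forward_multitarget(net, d, l, t)
        out2 = forward_multitarget(net, d, l, t)
        assert out1.shape == (2, 4)
        assert np.all(np.isfinite(out1))
        assert np.array_equal(out1, out2)

    def test_token_fusion_zero_head_gives_zeros(self, rng):
        net = build_net("token_fusion", np.random.default_rng(0), image_size=32,
                        patch_size=8, embed_dim=16, n_heads=2, n_layers=1)
        net.head.weight.data[...] = 0
        net.head.bias.data[...] = 0
        d, l, t = self._inputs(rng)
        assert np.allclose(forward_multitarget(net, d, l, t), 0.0)

    def test_baseline_forward_matches_hand_affine_map(self):
        """One averaging conv stage + linear head on a 2x2 image reproduces a
        hand-computed affine map of pixels and tabular encoding."""
        net = BaselineConcatNet(np.random.default_rng(1), backbone=(3,),
                                tabular_widths=(4,), head_widths=(), dropout=0.0)
        conv = net.backbone_d.blocks[0].layers[0]
        conv.weight.data[...] = 0
        for c in range(3):  # each filter averages its own channel's 2x2 block
            conv.weight.data[c, c, 1:, 1:] = 0.25
        conv.bias.data[...] = 0
        tab = net.tabular.mlp.net.layers[0]
        tab.weight.data[...] = np.eye(4)
        tab.bias.data[...] = 0
        head = net.head.layers[0]
        W = np.arange(40, dtype=float).reshape(10, 4) / 40.0
        head.weight.data[...] = W
        head.bias.data[...] = 0.1

        rng = np.random.default_rng(5)
        dorsal = np.abs(rng.normal(size=(1, 3, 2, 2)))  # ReLU-transparent
        lateral = np.abs(rng.normal(size=(1, 3, 2, 2)))
        raw_tab = np.array([[0.5, 0.0, 1.0, 0.0]])
        feats = np.concatenate([
            dorsal.mean(axis=(2, 3))[0], lateral.mean(axis=(2, 3))[0], raw_tab[0]
        ])
        expected = feats @ W + 0.1
        out = forward_multitarget(net, dorsal, lateral, raw_tab)
        assert np.allclose(out[0], expected, atol=1e-12)

    def test_token_permutation_with_positions_is_invariant(self, rng):
        net = TokenFusionNet(np.random.default_rng(2), image_size=32, patch_size=8,
                             embed_dim=16, n_heads=2, n_layers=2, dropout=0.0)
        net.eval()
        d, l, t = self._inputs(rng, n=1)
        tokens = net.tokenize(Tensor(d), Tensor(l), Tensor(t))
        out_ref = net.forward_tokens(tokens).data
        perm = np.concatenate([[0], 1 + np.random.default_rng(9).permutation(tokens.shape[1] - 1)])
        shuffled = Tensor(tokens.data[:, perm])
        out_perm = net.forward_tokens(shuffled).data
        assert np.allclose(out_ref, out_perm, atol=1e-10)

    def test_families_share_one_input_contract(self, rng):
        """Swappability: identical inputs are accepted by all families."""
        d, l, t = self._inputs(rng, n=3)
        outs = []
        for family, kwargs in [
            ("baseline_concat", {"backbone": (4,)}),
            ("attention_fusion", {"backbone": (4,)}),
            ("token_fusion", {"image_size": 32, "patch_size": 16, "embed_dim": 8,
                              "n_heads": 2, "n_layers": 1}),
        ]:
            net = build_net(family, np.random.default_rng(0), **kwargs)
            outs.append(forward_multitarget(net, d, l, t))
        assert all(o.shape == (3, 4) for o in outs)


class TestParameterCounts:
    def test_conv_backbone_count_matches_closed_form(self):
        net = BaselineConcatNet(np.random.default_rng(0), backbone=(8, 16),
                                tabular_widths=(4,), head_widths=(), dropout=0.0)
        conv1 = 8 * 3 * 9 + 8
        conv2 = 16 * 8 * 9 + 16
        tab = 4 * 4 + 4
        head = (2 * 16 + 4) * 4 + 4
        assert net.n_parameters() == conv1 + conv2 + tab + head

    def test_token_fusion_count_matches_closed_form(self):
        D, P, H, L, ratio = 16, 8, 2, 1, 2.0
        size = 32
        net = TokenFusionNet(np.random.default_rng(0), image_size=size, patch_size=P,
                             embed_dim=D, n_heads=H, n_layers=L, mlp_ratio=ratio,
                             tabular_widths=(8,), dropout=0.0)
        n_patch = (size // P) ** 2
        patch_embed = (3 * P * P * D + D) + n_patch * D + D  # proj + pos + view
        tab = (4 * 8 + 8) + (8 * D + D) + D  # mlp + proj + tab pos
        per_layer = 2 * 2 * D + 4 * (D * D + D) + (D * int(D * ratio) + int(D * ratio)) \
            + (int(D * ratio) * D + D)  # 2 LN + qkvo + ff
        final = 2 * D + (D * 4 + 4)  # final LN + head
        assert net.n_parameters() == 2 * patch_embed + tab + L * per_layer + final

    def test_shared_backbone_halves_visual_parameters(self):
        shared = BaselineConcatNet(np.random.default_rng(0), backbone=(8,), shared_backbone=True)
        separate = BaselineConcatNet(np.random.default_rng(0), backbone=(8,), shared_backbone=False)
        backbone_params = 8 * 3 * 9 + 8
        assert separate.n_parameters() - shared.n_parameters() == backbone_params


class TestAttentionFusionNet:
    def test_forward_shape_with_cbam(self):
        net = AttentionFusionNet(np.random.default_rng(4), backbone=(4, 8), dropout=0.0)
        rng = np.random.default_rng(1)
        out = forward_multitarget(net, rng.normal(size=(2, 3, 16, 16)),
                                  rng.normal(size=(2, 3, 16, 16)), rng.normal(size=(2, 4)))
        assert out.shape == (2, 4)
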