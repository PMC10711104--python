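import numpy as np
import pytest

from stemleaf import losses
from stemleaf.nn import Tensor
from stemleaf.segnet import (
    DECODER_WIDTHS,
    VGG16_BLOCKS,
    NetworkConfig,
    build_acunet,
    build_aspp,
    build_cca,
    count_parameters,
    load_vgg16_weights,
    predict,
    train,
)


def closed_form_baseline_params(num_classes=3) -> int:
    """Independent per-layer arithmetic for the full-width baseline."""
    total = 0
    cin = 3
    widths = [w for block in VGG16_BLOCKS for w in block]
    for w in widths:
        total += w * cin * 9 + w  # 3x3 conv + bias
        cin = w
    skips = [block[-1] for block in VGG16_BLOCKS]  # 64,128,256,512,512
    x = skips[-1]
    for width, skip in zip(DECODER_WIDTHS, reversed(skips[:-1])):
        total += width * (x + skip) * 9 + width
        total += width * width * 9 + width
        x = width
    total += num_classes * x + num_classes  # 1x1 head
    return total


TOY = dict(input_size=64, encoder_blocks=3, width_scale=0.25, seed=0)


class TestNetworkConfig:
    def test_input_size_divisibility_enforced(self):
        with pytest.raises(ValueError):
            NetworkConfig(input_size=100)

    def test_invalid_aspp_rates_rejected(self):
        with pytest.raises(ValueError):
            NetworkConfig(aspp_rates=(1, 2, 9))
        with pytest.raises(ValueError):
            NetworkConfig(aspp_rates=(2, 4, 8))

    def test_default_rates_are_the_retuned_schedule(self):
        assert NetworkConfig().aspp_rates == (1, 2, 7, 15)


class TestAspp:
    def test_branch_count_and_width(self):
        aspp = build_aspp(32, (1, 2, 7, 15), 16, rng=np.random.default_rng(0))
        assert aspp.branch_count == 5  # 1x1, three dilated, pooling
        x = Tensor(np.random.default_rng(1).random((2, 32, 8, 8)).astype(np.float32))
        out = aspp(x)
        assert out.shape == (2, 16, 8, 8)

    def test_spatial_preservation_various_sizes(self):
        aspp = build_aspp(8, (1, 2, 5), 8, rng=np.random.default_rng(0))
        for h, w in ((4, 4), (6, 10)):
            x = Tensor(np.zeros((1, 8, h, w), dtype=np.float32))
            assert aspp(x).shape[2:] == (h, w)

    def test_invalid_rates_propagate_verdict(self):
        with pytest.raises(ValueError, match="gridding"):
            build_aspp(8, (1, 2, 9), 8)


class TestCca:
    def test_shape_preserved(self):
        cca = build_cca(16, recurrence=2, reduction=8, rng=np.random.default_rng(0))
        x = Tensor(np.random.default_rng(1).random((2, 16, 6, 9)).astype(np.float32))
        assert cca(x).shape == (2, 16, 6, 9)

    def test_indivisible_channels_rejected(self):
        with pytest.raises(ValueError):
            build_cca(10, reduction=8)

    def test_attention_weights_sum_to_one(self):
        cca = build_cca(16, rng=np.random.default_rng(0))
        x = Tensor(np.random.default_rng(1).random((1, 16, 5, 7)).astype(np.float32))
        w = cca.attention_weights(x)
        assert w.shape == (1, 5, 7, 7 + 5)
        assert np.allclose(w.sum(axis=-1), 1.0, atol=1e-5)
        assert (w >= 0).all()

    def test_two_recurrences_give_full_image_context(self):
        """Perturbing any single position must change every output position."""
        cca = build_cca(8, recurrence=2, reduction=4, rng=np.random.default_rng(0))
        rng = np.random.default_rng(1)
        x = rng.random((1, 8, 8, 8)).astype(np.float64)
        base = cca(Tensor(x)).data
        for r, c in ((0, 0), (3, 5), (7, 7)):
            xp = x.copy()
            xp[0, :, r, c] += 0.5
            diff = np.abs(cca(Tensor(xp)).data - base).sum(axis=1)[0]
            assert (diff > 1e-12).all(), f"perturbation at {(r, c)} did not reach all positions"

    def test_single_recurrence_does_not_reach_everywhere(self):
        cca = build_cca(8, recurrence=1, reduction=4, rng=np.random.default_rng(0))
        rng = np.random.default_rng(1)
        x = rng.random((1, 8, 8, 8)).astype(np.float64)
        base = cca(Tensor(x)).data
        xp = x.copy()
        xp[0, :, 0, 0] += 0.5
        diff = np.abs(cca(Tensor(xp)).data - base).sum(axis=1)[0]
        assert diff[7, 7] < 1e-12  # off-cross position untouched after one pass


class TestBuildAcunet:
    def test_baseline_parameter_count(self):
        model = build_acunet(NetworkConfig(use_aspp=False, use_cca=False))
        expected = closed_form_baseline_params()
        assert expected == 24_891_267  # 24.891 M
        assert count_parameters(model) == expected

    def test_encoder_alone_parameter_count(self):
        model = build_acunet(NetworkConfig(use_aspp=False, use_cca=False))
        enc = sum(
            p.data.size for block in model.encoder_blocks for p in block.parameters()
        )
        assert enc == 14_714_688

    def test_head_parameter_count(self):
        model = build_acunet(NetworkConfig(use_aspp=False, use_cca=False))
        assert count_parameters(model.head) == 64 * 3 + 3 == 195

    def test_aspp_and_cca_add_parameters(self):
        base = count_parameters(build_acunet(NetworkConfig(use_aspp=False, use_cca=False, **{})))
        with_aspp = count_parameters(build_acunet(NetworkConfig(use_cca=False)))
        full = count_parameters(build_acunet(NetworkConfig()))
        assert base < with_aspp < full

    def test_toy_forward_prob_map(self):
        model = build_acunet(NetworkConfig(num_classes=3, **TOY))
        img = np.random.default_rng(0).random((64, 64, 3)).astype(np.float32)
        probs = predict(model, img)
        assert probs.shape == (64, 64, 3)
        assert np.allclose(probs.sum(axis=-1), 1.0, atol=1e-5)
        assert (probs >= 0).all() and (probs <= 1).all()

    def test_spatial_dimensions_preserved_for_rectangular_input(self):
        model = build_acunet(NetworkConfig(input_size=32, encoder_blocks=2, width_scale=0.25))
        img = np.random.default_rng(0).random((32, 32, 3)).astype(np.float32)
        assert predict(model, img).shape[:2] == (32, 32)


class TestVgg16Interop:
    def test_name_mapped_loading_then_forward(self):
        model = build_acunet(
            NetworkConfig(input_size=32, use_aspp=False, use_cca=False)
        )
        rng = np.random.default_rng(0)
        state = {}
        cin = 3
        idx = (0, 2, 5, 7, 10, 12, 14, 17, 19, 21, 24, 26, 28)
        widths = [w for block in VGG16_BLOCKS for w in block]
        for i, w in zip(idx, widths):
            state[f"features.{i}.weight"] = rng.standard_normal((w, cin, 3, 3)) * 0.01
            state[f"features.{i}.bias"] = np.zeros(w)
            cin = w
        load_vgg16_weights(model, state)
        got = model.encoder_blocks[0].convs[0].weight.data
        assert np.allclose(got, state["features.0.weight"], atol=1e-6)
        img = np.random.default_rng(1).random((32, 32, 3)).astype(np.float32)
        probs = predict(model, img)
        assert np.allclose(probs.sum(axis=-1), 1.0, atol=1e-5)

    def test_truncated_encoder_rejects_checkpoint(self):
        model = build_acunet(NetworkConfig(**TOY))
        with pytest.raises(ValueError):
            load_vgg16_weights(model, {})


class TestTraining:
    @staticmethod
    def _tiny_data(n=6, size=32, seed=0):
        from stemleaf.synthdata import SceneParams, generate_scene

        imgs, masks = [], []
        for i in range(n):
            img, mask = generate_scene(
                SceneParams(size=size, seed=seed + i, leaf_major=(20, 28), leaf_minor=(10, 14))
            )
            imgs.append(img.astype(np.float32) / 255.0)
            masks.append(mask)
        return np.stack(imgs), np.stack(masks)

    def test_zero_lr_keeps_parameters(self):
        imgs, masks = self._tiny_data()
        model = build_acunet(NetworkConfig(num_classes=3, input_size=32, encoder_blocks=2, width_scale=0.25))
        before = {k: v.copy() for k, v in model.state_dict().items()}
        train(model, imgs, masks, epochs=1, batch_size=2, lr=0.0, loss="dice", seed=0)
        after = model.state_dict()
        for key in before:
            if "running" in key:
                continue
            assert np.array_equal(before[key], after[key]), key

    def test_history_length_and_loss_decreases(self):
        imgs, masks = self._tiny_data()
        model = build_acunet(NetworkConfig(num_classes=3, input_size=32, encoder_blocks=2, width_scale=0.25))
        res = train(model, imgs, masks, epochs=4, batch_size=2, seed=0)
        assert len(res.history) == 4
        assert res.history[-1]["train_loss"] < res.history[0]["train_loss"]

    def test_empty_dataset_rejected(self):
        model = build_acunet(NetworkConfig(num_classes=3, input_size=32, encoder_blocks=2, width_scale=0.25))
        with pytest.raises(ValueError):
            train(model, np.zeros((0, 32, 32, 3)), np.zeros((0, 32, 32), dtype=int))

    def test_shape_mismatch_rejected(self):
        model = build_acunet(NetworkConfig(num_classes=3, input_size=32, encoder_blocks=2, width_scale=0.25))
        with pytest.raises(ValueError):
            train(model, np.zeros((2, 32, 32, 3)), np.zeros((2, 16, 16), dtype=int))

    def test_training_is_seed_deterministic(self):
        imgs, masks = self._tiny_data(n=4)
        results = []
        for _ in range(2):
            model = build_acunet(
                NetworkConfig(num_classes=3, input_size=32, encoder_blocks=2, width_scale=0.25, seed=3)
            )
            res = train(model, imgs, masks, epochs=2, batch_size=2, seed=11)
            results.append(res.history[-1]["train_loss"])
        assert results[0] == results[1]
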