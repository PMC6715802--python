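"""Model zoo: block-grammar builders, geometry and parameter oracles,
patch-to-whole-image conversion and heatmap equivalence."""

import numpy as np
import pytest

from mammofcn import models, nn
from mammofcn.models import (BackboneSpec, BlockSpec, SpecError, TopSpec,
                             build_patch_classifier, count_parameters,
                             heatmap_of, random_valid_trunk, receptive_field,
                             sliding_window_reference, tiny_backbone,
                             to_whole_image)


class TestBuilders:
    def test_tiny_preset_outputs_probabilities(self):
        handle = build_patch_classifier(tiny_backbone(64, widths=(8, 16)),
                                        seed=0)
        out = handle.predict(np.random.default_rng(0).random((3, 1, 64, 64)))
        assert out.shape == (3, 5)
        assert np.allclose(out.sum(axis=1), 1.0, atol=1e-6)
        assert (out >= 0).all()

    def test_vgg16_preset_runs_a_224_patch(self):
        handle = build_patch_classifier(models.vgg16_backbone(), seed=0)
        out = handle.predict(np.random.default_rng(1).random((1, 1, 224, 224)))
        assert out.shape == (1, 5)
        assert np.isclose(out.sum(), 1.0, atol=1e-5)

    def test_resnet50_preset_unit_counts(self):
        handle = build_patch_classifier(models.resnet50_backbone(), seed=0)
        units = [lay for lay in handle.net.layers
                 if isinstance(lay, nn.BottleneckUnit)]
        # bottleneck units per stage: 3+4+6+3; weighted layers 1 + 3*16 + 1 = 50
        assert len(units) == 16
        convs = sum(isinstance(lay, nn.Conv2d)
                    for lay in handle.net.leaf_layers())
        dense = sum(isinstance(lay, nn.Dense)
                    for lay in handle.net.leaf_layers())
        # 53 convolutions include the stem and 4 projection shortcuts; the
        # 50 weighted layers of the naming are stem + 48 unit convs + FC
        assert convs == 53 and dense == 1
        assert 1 + 3 * 16 + 1 == 50

    def test_malformed_spec_reports_block(self):
        with pytest.raises(SpecError):
            BlockSpec("vgg", (0, 1))
        with pytest.raises(SpecError):
            BlockSpec.parse("512y3")
        with pytest.raises(SpecError):
            BackboneSpec(blocks=[])

    def test_grammar_roundtrip(self):
        for text in ("256x1", "[512-512-1024]x2"):
            assert BlockSpec.parse(text).grammar() == text

    def test_spec_yaml_dict_roundtrip(self):
        spec = models.resnet50_backbone()
        again = models.backbone_from_dict(models.backbone_to_dict(spec))
        assert [b.grammar() for b in again.blocks] == \
            [b.grammar() for b in spec.blocks]
        assert again.stem == "resnet"


class TestReceptiveField:
    def test_worked_chain_rf224_stride32_plus_3x3(self):
        # adding one 3x3 conv on a (rf 224, stride 32) trunk widens each
        # side by (3-1)*32
        assert receptive_field([(32, 32), (7, 1)]) == (224, 32)
        assert receptive_field([(32, 32), (7, 1), (3, 1)]) == (288, 32)

    def test_single_and_stacked_3x3(self):
        assert receptive_field([(3, 1)]) == (3, 1)
        assert receptive_field([(3, 1), (3, 1)]) == (5, 1)

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_influence_tracing_oracle(self, seed):
        # random <=5-layer all-positive-weight conv chains: the input
        # support of one output unit's gradient is exactly the receptive
        # field
        rng = np.random.default_rng(seed)
        layers = []
        ch = 1
        for _ in range(int(rng.integers(1, 6))):
            k = int(rng.choice([1, 3, 5]))
            s = int(rng.choice([1, 2]))
            width = int(rng.integers(1, 4))
            conv = nn.Conv2d(ch, width, k, s, "valid", bias=False, rng=rng)
            conv.w.data[...] = np.abs(conv.w.data) + 0.1
            layers.append(conv)
            ch = width
        net = nn.Sequential(layers)
        rf, stride = receptive_field(net)
        size = rf + 2 * stride  # room for >1 output position
        x = np.zeros((1, 1, size, size), dtype=np.float32)
        out = net.forward(x, train=True)
        dout = np.zeros_like(out)
        dout[0, :, 0, 0] = 1.0
        grad = net.backward(dout)
        ys, xs = np.nonzero(np.abs(grad[0, 0]) > 0)
        assert ys.max() - ys.min() + 1 == rf
        assert xs.max() - xs.min() + 1 == rf

    def test_unsupported_input_rejected(self):
        with pytest.raises(Exception):
            receptive_field([("not", "geometry", "tuple")])


class TestCountParameters:
    def test_single_conv_with_bias(self):
        net = nn.Sequential([nn.Conv2d(1, 8, 3, bias=True)])
        assert count_parameters(net) == 3 * 3 * 1 * 8 + 8 == 80

    def test_counts_additive_and_freeze_invariant(self):
        handle = build_patch_classifier(tiny_backbone(32), seed=0)
        total = count_parameters(handle)
        per_layer = sum(sum(p.size for p in lay.params())
                        for lay in handle.net.layers)
        assert total == per_layer
        for lay in handle.net.leaf_layers():
            lay.trainable = False
        assert count_parameters(handle) == total

    def test_head_exclusion_drops_fc(self):
        handle = build_patch_classifier(tiny_backbone(32, widths=(8, 16)),
                                        seed=0)
        diff = count_parameters(handle) - count_parameters(handle,
                                                           include_head=False)
        assert diff == 16 * 5 + 5  # GAP has no weights; FC head 16->5


class TestConversion:
    @pytest.fixture()
    def patch_handle(self):
        return build_patch_classifier(tiny_backbone(32, widths=(8, 16)),
                                      seed=1)

    def test_conv_top_maps_image_to_two_probabilities(self, patch_handle):
        top = TopSpec(variant="conv_blocks_no_heatmap",
                      top_blocks=[BlockSpec("vgg", (8, 1), batch_norm=True)])
        whole = to_whole_image(patch_handle, top)
        out = whole.predict(np.random.default_rng(0).random((2, 1, 96, 96)))
        assert out.shape == (2, 2)
        assert np.allclose(out.sum(axis=1), 1.0, atol=1e-6)

    def test_heatmap_conv_weights_copied_from_head(self, patch_handle):
        top = TopSpec(variant="heatmap_then_conv_blocks",
                      heatmap_activation="relu",
                      top_blocks=[BlockSpec("vgg", (8, 1), batch_norm=True)])
        whole = to_whole_image(patch_handle, top)
        fc = patch_handle.net.layers[-2]
        conv = next(lay for lay in whole.net.layers
                    if isinstance(lay, nn.Conv2d) and lay.out_ch == 5)
        assert np.array_equal(conv.w.data[:, :, 0, 0], fc.w.data.T)
        assert np.array_equal(conv.b.data, fc.b.data)

    def test_fc_top_with_pool5_and_shortcut_constructible(self, patch_handle):
        top = TopSpec(variant="heatmap_maxpool_fc_shortcut", pool_size=5,
                      fc_sizes=(64, 32), heatmap_activation="softmax")
        whole = to_whole_image(patch_handle, top, image_size=(144, 112))
        out = whole.predict(np.random.default_rng(0).random((1, 1, 144, 112)))
        assert out.shape == (1, 2)
        assert np.isclose(out.sum(), 1.0, atol=1e-6)
        assert any(isinstance(lay, nn.FcTopShortcut)
                   for lay in whole.net.layers)

    def test_fc_top_without_image_size_rejected(self, patch_handle):
        top = TopSpec(variant="heatmap_maxpool_fc_shortcut")
        with pytest.raises(SpecError):
            to_whole_image(patch_handle, top)

    def test_trunk_activations_preserved_bit_exactly(self, patch_handle):
        x = np.random.default_rng(3).random((1, 1, 32, 32)).astype(np.float32)
        trunk_len = len(patch_handle.net.layers) - 3
        before = nn.Sequential(
            patch_handle.net.layers[:trunk_len]).forward(x)
        top = TopSpec(variant="conv_blocks_no_heatmap",
                      top_blocks=[BlockSpec("vgg", (8, 1), batch_norm=True)])
        whole = to_whole_image(patch_handle, top)
        after = nn.Sequential(
            whole.net.layers[:whole.source_layer_count]).forward(x)
        assert np.array_equal(before, after)


class TestHeatmap:
    def test_grid_shape_for_rf224_stride32_on_full_frame(self):
        # valid-padding toy trunk with rf 224, stride 32: a 32/32 conv then
        # a 7x7 conv; grid is floor((dim-224)/32)+1 per side
        rng = np.random.default_rng(0)
        layers = [nn.Conv2d(1, 4, 32, 32, "valid", rng=rng),
                  nn.ReLU(),
                  nn.Conv2d(4, 4, 7, 1, "valid", rng=rng),
                  nn.ReLU(),
                  nn.GlobalAvgPool(),
                  nn.Dense(4, 5, rng=rng),
                  nn.Softmax()]
        handle = models.NetworkHandle(net=nn.Sequential(layers), kind="patch",
                                      n_classes=5, input_size=224,
                                      trunk_channels=4)
        assert receptive_field([(32, 32), (7, 1)]) == (224, 32)
        hm = heatmap_of(np.zeros((1152, 896), dtype=np.float32), handle)
        assert hm.grid.shape == (30, 22, 5)
        assert hm.grid_valid_padding == (30, 22)
        assert hm.grid_same_padding == (36, 28)

    def test_softmax_cells_normalized_and_relu_nonnegative(self):
        handle = random_valid_trunk(np.random.default_rng(5))
        img = np.random.default_rng(6).random((120, 120)).astype(np.float32)
        sm = heatmap_of(img, handle, activation="softmax")
        assert np.allclose(sm.grid.sum(axis=2), 1.0, atol=1e-6)
        rl = heatmap_of(img, handle, activation="relu")
        assert rl.grid.min() >= 0.0

    def test_image_smaller_than_receptive_field_rejected(self):
        handle = random_valid_trunk(np.random.default_rng(2))
        small = np.zeros((handle.input_size - 1, handle.input_size - 1),
                         dtype=np.float32)
        with pytest.raises(SpecError):
            heatmap_of(small, handle)

    def test_sliding_window_matches_fully_convolutional(self):
        rng = np.random.default_rng(11)
        for _ in range(3):
            handle = random_valid_trunk(rng)
            img = rng.random((150, 150)).astype(np.float32)
            fc = heatmap_of(img, handle, activation="softmax")
            sw = sliding_window_reference(img, handle)
            assert sw.grid.shape == fc.grid.shape
            assert np.abs(sw.grid - fc.grid).max() < 1e-5

    def test_constant_image_gives_constant_heatmap(self):
        handle = random_valid_trunk(np.random.default_rng(4))
        img = np.full((140, 140), 0.5, dtype=np.float32)
        hm = heatmap_of(img, handle)
        assert np.allclose(hm.grid, hm.grid[0, 0], atol=1e-6)


class TestWeightsIO:
    def test_save_load_roundtrip_preserves_predictions(self, tmp_path):
        handle = build_patch_classifier(tiny_backbone(32), seed=7)
        x = np.random.default_rng(0).random((2, 1, 32, 32))
        before = handle.predict(x)
        path = tmp_path / "w.npz"
        models.save_weights(handle.net, path)
        other = build_patch_classifier(tiny_backbone(32), seed=99)
        models.load_weights(other.net, path)
        assert np.allclose(other.predict(x), before)
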