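"""RDU-Net blocks, model contracts, training recovery, mask utilities."""

import numpy as np
import pytest

from bronchoscore.ctslice import LobeMask
from bronchoscore.lobeseg import (
    RDUNetConfig,
    build_rdunet,
    dice_and_iou,
    extract_lobe_images,
    load_checkpoint,
    residual_dilated_block,
    save_checkpoint,
    segment_lobes,
    train_segmenter,
)
from bronchoscore.nn import Tensor
from bronchoscore.phantom import PhantomSpec, generate_phantom


def conv_chain_footprint(rates_kernels):
    """Dependency-traced receptive-field offsets of stacked convolutions."""
    offsets = {(0, 0)}
    for rate, kernel in rates_kernels:
        half = kernel // 2
        taps = range(-half, half + 1)
        offsets = {
            (y + rate * dy, x + rate * dx)
            for (y, x) in offsets
            for dy in taps
            for dx in taps
        }
    return offsets


def bbox_of(offsets):
    ys = [y for y, _ in offsets]
    xs = [x for _, x in offsets]
    return max(ys) - min(ys) + 1, max(xs) - min(xs) + 1


class TestConfig:
    def test_cycle_length_must_match_depth(self):
        with pytest.raises(ValueError):
            RDUNetConfig(depth=4, dilation_cycle=(1, 2, 4, 2, 1))

    def test_default_cycle_is_small_large_small(self):
        assert RDUNetConfig().dilation_cycle == (1, 2, 4, 2, 1)

    def test_round_trips_through_dict(self):
        cfg = RDUNetConfig(depth=3, base_channels=4, dilation_cycle=(1, 2, 1), n_classes=3)
        assert RDUNetConfig.from_dict(cfg.to_dict()) == cfg


class TestResidualBlock:
    def test_identity_at_zero_residual(self):
        blk = residual_dilated_block(8, 8, 4, np.random.default_rng(0))
        blk.zero_residual()
        x = Tensor(np.random.default_rng(1).normal(0, 1, (1, 8, 16, 16)))
        assert np.allclose(blk(x).data, x.data)

    def test_output_shape_contract(self):
        blk = residual_dilated_block(16, 24, 2, np.random.default_rng(0))
        x = Tensor(np.zeros((1, 16, 64, 64)))
        assert blk(x).shape == (1, 24, 64, 64)

    def test_invalid_rate_rejected(self):
        with pytest.raises(ValueError):
            residual_dilated_block(4, 4, 0)

    def test_dilated_footprint_matches_large_dense_kernel(self):
        # one 3x3 conv at rate 4 spans the same 9x9 box as one dense 9x9 conv
        assert bbox_of(conv_chain_footprint([(4, 3)])) == (9, 9)
        assert bbox_of(conv_chain_footprint([(1, 9)])) == (9, 9)
        # and a block's two stacked convs keep the equivalence (17x17 both ways)
        assert bbox_of(conv_chain_footprint([(4, 3), (4, 3)])) == bbox_of(
            conv_chain_footprint([(1, 9), (1, 9)])
        )


class TestModel:
    def test_forward_shape_contract(self):
        cfg = RDUNetConfig(depth=4, base_channels=4, dilation_cycle=(1, 2, 4, 2), n_classes=5)
        model = build_rdunet(cfg, seed=0)
        out = model(Tensor(np.zeros((1, 1, 64, 64))))
        assert out.shape == (1, 5, 64, 64)
        assert model.n_parameters() > 0

    def test_too_small_input_raises_clear_error(self):
        cfg = RDUNetConfig(depth=4, base_channels=4, dilation_cycle=(1, 2, 4, 2), n_classes=5)
        model = build_rdunet(cfg, seed=0)
        with pytest.raises(ValueError, match="smaller than"):
            model(Tensor(np.zeros((1, 1, 4, 4))))

    def test_classic_pooling_variant_keeps_shape_contract(self):
        cfg = RDUNetConfig(depth=3, base_channels=4, dilation_cycle=(1, 2, 1),
                           n_classes=5, use_pooling=True)
        model = build_rdunet(cfg, seed=0)
        out = model(Tensor(np.random.default_rng(0).normal(0, 1, (1, 1, 32, 32))))
        assert out.shape == (1, 5, 32, 32)

    def test_zero_head_gives_uniform_scores(self):
        cfg = RDUNetConfig(depth=3, base_channels=4, dilation_cycle=(1, 2, 1), n_classes=5)
        model = build_rdunet(cfg, seed=0)
        model.head.weight.data[...] = 0.0
        model.head.bias.data[...] = 0.0
        out = model(Tensor(np.random.default_rng(0).normal(0, 1, (1, 1, 32, 32))))
        assert np.allclose(out.data, out.data[:, :1])

    def test_every_block_in_model_is_identity_at_zero_residual(self):
        cfg = RDUNetConfig(depth=3, base_channels=4, dilation_cycle=(1, 2, 1), n_classes=5)
        model = build_rdunet(cfg, seed=0)
        rng = np.random.default_rng(2)
        for blk in model.enc_blocks + model.dec_blocks:
            blk.zero_residual()
            cin = blk.conv1.weight.data.shape[1]
            x = Tensor(rng.normal(0, 1, (1, cin, 16, 16)))
            out = blk(x)
            if blk.project is None:
                assert np.allclose(out.data, x.data)
            else:  # channel change: the shortcut is the 1x1 projection alone
                assert np.allclose(out.data, blk.project(x).data)


def tiny_dataset(n, size=32, seed0=0):
    samples = [
        generate_phantom(
            PhantomSpec(image_size=size, n_lesions=0, n_distractor_vessels=1, seed=seed0 + s)
        )
        for s in range(n)
    ]
    return [(s.image, s.lobe_mask) for s in samples], samples


class TestTraining:
    def test_loss_trace_and_determinism(self):
        ds, _ = tiny_dataset(2)
        cfg = RDUNetConfig(depth=3, base_channels=4, dilation_cycle=(1, 2, 1), n_classes=5)
        m1, t1 = train_segmenter(build_rdunet(cfg, seed=0), ds, epochs=3, seed=7)
        m2, t2 = train_segmenter(build_rdunet(cfg, seed=0), ds, epochs=3, seed=7)
        assert len(t1) == 3
        assert t1 == t2  # fully deterministic given the seed

    def test_empty_dataset_rejected(self):
        cfg = RDUNetConfig(depth=3, base_channels=4, dilation_cycle=(1, 2, 1), n_classes=5)
        with pytest.raises(ValueError):
            train_segmenter(build_rdunet(cfg), [], epochs=1)

    def test_overfit_single_sample_segments_it_well(self):
        ds, samples = tiny_dataset(1, size=32, seed0=5)
        cfg = RDUNetConfig(depth=3, base_channels=8, dilation_cycle=(1, 2, 1), n_classes=5)
        model = build_rdunet(cfg, seed=0)
        model, losses = train_segmenter(model, ds, epochs=60, lr=3e-3, seed=0)
        assert losses[-1] < losses[0]
        pred = segment_lobes(model, samples[0].image)
        scores = dice_and_iou(pred, samples[0].lobe_mask)
        mean_iou = np.mean([v["iou"] for v in scores.values()])
        assert mean_iou >= 0.9

    def test_checkpoint_round_trip(self, tmp_path):
        ds, samples = tiny_dataset(1)
        cfg = RDUNetConfig(depth=3, base_channels=4, dilation_cycle=(1, 2, 1), n_classes=5)
        model, _ = train_segmenter(build_rdunet(cfg, seed=0), ds, epochs=1, seed=0)
        save_checkpoint(model, tmp_path / "seg.npz")
        back = load_checkpoint(tmp_path / "seg.npz")
        a = segment_lobes(model, samples[0].image)
        b = segment_lobes(back, samples[0].image)
        assert np.array_equal(a.labels, b.labels)


class TestSegmentation:
    def test_labels_within_configured_classes(self):
        cfg = RDUNetConfig(depth=3, base_channels=4, dilation_cycle=(1, 2, 1), n_classes=5)
        model = build_rdunet(cfg, seed=0)
        mask = segment_lobes(model, np.zeros((32, 32)) + 100.0)
        assert set(np.unique(mask.labels)) <= set(range(5))

    def test_all_background_prediction_scores_zero_iou(self):
        truth = np.zeros((16, 16), dtype=np.int32)
        truth[4:8, 4:8] = 2
        pred = np.zeros_like(truth)
        scores = dice_and_iou(pred, truth)
        assert scores[2]["iou"] == 0.0


class TestLobeCrops:
    def test_square_lobe_crop_is_tight(self):
        labels = np.zeros((32, 32), dtype=np.int32)
        labels[5:15, 8:18] = 1
        img = np.random.default_rng(0).uniform(0, 255, (32, 32))
        crops = extract_lobe_images(img, labels)
        assert crops[1].pixels.shape == (10, 10)
        assert crops[1].offset == (5, 8)

    def test_pixel_sum_conserved(self, small_phantom):
        img = small_phantom.image.pixels
        labels = small_phantom.lobe_mask.labels
        crops = extract_lobe_images(img, small_phantom.lobe_mask)
        total = sum(c.pixels.sum() for c in crops.values())
        assert total == pytest.approx(img[labels > 0].sum())

    def test_paste_back_reconstructs_masked_image(self, small_phantom):
        img = small_phantom.image.pixels
        labels = small_phantom.lobe_mask.labels
        crops = extract_lobe_images(img, small_phantom.lobe_mask)
        recon = np.zeros_like(img)
        for c in crops.values():
            y, x = c.offset
            h, w = c.pixels.shape
            recon[y : y + h, x : x + w] += c.pixels
        assert np.allclose(recon, np.where(labels > 0, img, 0.0))

    def test_absent_lobe_omitted(self):
        labels = np.zeros((20, 20), dtype=np.int32)
        labels[2:6, 2:6] = 3
        crops = extract_lobe_images(np.ones((20, 20)), labels)
        assert set(crops) == {3}

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            extract_lobe_images(np.ones((10, 10)), np.zeros((12, 12), dtype=np.int32))


class TestDiceIou:
    def test_perfect_prediction(self):
        labels = np.zeros((16, 16), dtype=np.int32)
        labels[2:8, 2:8] = 1
        scores = dice_and_iou(labels, labels)
        assert scores[1] == {"iou": 1.0, "dice": 1.0}

    def test_disjoint_prediction(self):
        a = np.zeros((16, 16), dtype=np.int32)
        b = np.zeros_like(a)
        a[0:4, 0:4] = 1
        b[8:12, 8:12] = 1
        assert dice_and_iou(a, b)[1]["iou"] == 0.0

    def test_half_overlap_squares(self):
        # equal 4x8 rectangles offset by half their width: IOU 1/3, Dice 1/2
        a = np.zeros((16, 16), dtype=np.int32)
        b = np.zeros_like(a)
        a[0:4, 0:8] = 1
        b[0:4, 4:12] = 1
        s = dice_and_iou(a, b)[1]
        assert s["iou"] == pytest.approx(1 / 3)
        assert s["dice"] == pytest.approx(1 / 2)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            dice_and_iou(np.zeros((4, 4), dtype=int), np.zeros((5, 5), dtype=int))

    def test_accepts_lobemask_wrappers(self):
        labels = np.zeros((16, 16), dtype=np.int32)
        labels[1:5, 1:5] = 2
        wrapped = LobeMask(labels=labels, lobe_table={2: "left_lower"})
        assert dice_and_iou(wrapped, labels)[2]["iou"] == 1.0
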