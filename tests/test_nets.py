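"""Network builders, losses, and the training loop."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from aclloc import nets
from aclloc.nn.layers import BatchNorm, GroupNorm
from aclloc.targets import HeatmapTarget


def _param_count(model):
    return sum(p.value.size for p in model.params())


class TestSegNet:
    def test_output_shape_contract(self):
        cfg = nets.NetConfig(depth=3, base_channels=4, n_outputs=4, input_shape=(16, 16, 8))
        model = nets.build_seg_net(cfg, seed=0)
        out = model.forward(np.zeros((16, 16, 8), dtype=np.float32))
        assert out.shape == (4, 16, 16, 8)

    def test_forward_deterministic(self):
        cfg = nets.NetConfig(depth=2, base_channels=4, n_outputs=2, input_shape=(8, 8, 8))
        model = nets.build_seg_net(cfg, seed=1)
        x = np.random.default_rng(0).normal(size=(8, 8, 8)).astype(np.float32)
        np.testing.assert_array_equal(model.forward(x), model.forward(x))

    def test_doubling_channels_quadruples_parameters(self):
        """Conv-dominated nets scale parameters ~4x with 2x channels."""
        small = nets.build_seg_net(
            nets.NetConfig(depth=3, base_channels=8, n_outputs=4, input_shape=(16, 16, 8))
        )
        big = nets.build_seg_net(
            nets.NetConfig(depth=3, base_channels=16, n_outputs=4, input_shape=(16, 16, 8))
        )
        ratio = _param_count(big) / _param_count(small)
        assert 3.2 <= ratio <= 4.8

    def test_indivisible_input_rejected(self):
        cfg = nets.NetConfig(depth=3, base_channels=4, input_shape=(16, 16, 8))
        model = nets.build_seg_net(cfg)
        with pytest.raises(ValueError, match="divisible"):
            model.forward(np.zeros((15, 16, 8), dtype=np.float32))

    @settings(max_examples=8, deadline=None, derandomize=True)
    @given(
        depth=st.integers(min_value=1, max_value=3),
        base=st.sampled_from([2, 4]),
        n_out=st.integers(min_value=1, max_value=3),
    )
    def test_shape_contract_random_configs(self, depth, base, n_out):
        size = 8 * 2 ** (depth - 1) // 2 ** (depth - 1) * 2 ** (depth - 1)
        shape = (2 ** (depth - 1) * 4, 2 ** (depth - 1) * 2, 2 ** (depth - 1) * 2)
        cfg = nets.NetConfig(depth=depth, base_channels=base, n_outputs=n_out, input_shape=shape)
        model = nets.build_seg_net(cfg, seed=0)
        out = model.forward(np.zeros(shape, dtype=np.float32))
        assert out.shape == (n_out, *shape)
        assert out.min() >= 0.0 and out.max() <= 1.0


class TestHeatmapNet:
    def test_output_in_unit_interval_full_resolution(self):
        cfg = nets.NetConfig(depth=3, base_channels=4, input_shape=(16, 16, 8))
        model = nets.build_heatmap_net(cfg, seed=2)
        x = np.random.default_rng(1).normal(size=(16, 16, 8)).astype(np.float32)
        out = model.forward(x)
        assert out.shape == (1, 16, 16, 8)
        assert out.min() >= 0.0 and out.max() <= 1.0

    def test_group_norm_present_batch_norm_absent(self):
        cfg = nets.NetConfig(depth=2, base_channels=4, norm="group", input_shape=(8, 8, 8))
        model = nets.build_heatmap_net(cfg)
        layers = list(model.iter_layers())
        assert any(type(l) is GroupNorm for l in layers)
        assert not any(type(l) is BatchNorm for l in layers)

    def test_batch_norm_option(self):
        cfg = nets.NetConfig(depth=2, base_channels=4, norm="batch", input_shape=(8, 8, 8))
        model = nets.build_heatmap_net(cfg)
        assert any(type(l) is BatchNorm for l in model.iter_layers())


@pytest.fixture(scope="module")
def slice_model():
    cfg = nets.NetConfig(
        depth=3, base_channels=2, input_shape=(6, 256, 256), downsampled_axes=(1, 2)
    )
    return nets.build_slice_net(cfg, seed=3)


class TestSliceNet:

    def test_softmax_output(self, slice_model):
        x = np.random.default_rng(2).normal(size=(6, 256, 256)).astype(np.float32)
        probs = slice_model.forward(x)
        assert probs.shape == (6,)
        assert probs.sum() == pytest.approx(1.0, abs=1e-6)
        assert np.all(probs >= 0)

    def test_eight_halvings_collapse_inplane(self, slice_model):
        """256 -> 1 after eight in-plane poolings; the slice count survives."""
        x = np.zeros((6, 256, 256), dtype=np.float32)
        body_out = slice_model.body.forward(x[None])
        assert body_out.shape == (1, 6, 1, 1)

    def test_slice_permutation_equivariance(self, slice_model):
        """1x3x3 convs never mix slices, so permuting slices permutes scores."""
        rng = np.random.default_rng(4)
        x = rng.normal(size=(6, 256, 256)).astype(np.float32)
        perm = np.array([3, 0, 5, 1, 4, 2])
        base = slice_model.forward(x)
        permuted = slice_model.forward(x[perm])
        np.testing.assert_allclose(permuted, base[perm], atol=1e-5)

    def test_wrong_input_shape_rejected(self, slice_model):
        with pytest.raises(ValueError):
            slice_model.forward(np.zeros((5, 256, 256), dtype=np.float32))


class TestDetector:
    def _blob_image(self, rng, size=64, sigma=2.5):
        center = rng.uniform(10, size - 10, 2)
        ii, jj = np.meshgrid(np.arange(size), np.arange(size), indexing="ij")
        img = np.exp(-((ii - center[0]) ** 2 + (jj - center[1]) ** 2) / (2 * sigma**2))
        img += rng.normal(0, 0.05, (size, size))
        return img.astype(np.float32), center

    def test_decode_inside_bounds_and_deterministic(self):
        cfg = nets.NetConfig(depth=1, base_channels=4, input_shape=(64, 64))
        model = nets.build_detector(cfg, seed=5)
        rng = np.random.default_rng(3)
        img, _ = self._blob_image(rng)
        raw = model.forward(img)
        center, score = model.decode(raw)
        assert 0 <= center[0] <= 63 and 0 <= center[1] <= 63
        assert 0.0 <= score <= 1.0
        raw2 = model.forward(img)
        np.testing.assert_array_equal(raw, raw2)

    def test_trains_to_subpixel_blob_detection(self):
        """30 epochs on 64 blob images -> mean center error < 2 px held out."""
        rng = np.random.default_rng(6)
        data = [self._blob_image(rng) for _ in range(80)]
        train, test = data[:64], data[64:]
        cfg = nets.NetConfig(depth=1, base_channels=4, input_shape=(64, 64))
        model = nets.build_detector(cfg, seed=6)
        model, history = nets.train(
            model, train, nets.TrainConfig(epochs=30, lr=0.05, seed=6)
        )
        errors = []
        for img, center in test:
            pred, _ = model.decode(model.forward(img))
            errors.append(np.linalg.norm(pred - center))
        assert np.mean(errors) < 2.0


class TestDiceFocalLoss:
    def test_perfect_binary_match_near_zero(self):
        rng = np.random.default_rng(7)
        t = (rng.uniform(size=(8, 8, 8)) > 0.9).astype(np.float32)
        assert nets.dice_focal_loss(t, t) <= 1e-3

    def test_gamma_zero_alpha_half_is_half_bce(self):
        rng = np.random.default_rng(8)
        p = rng.uniform(0.05, 0.95, (6, 6, 6))
        t = (rng.uniform(size=(6, 6, 6)) > 0.7).astype(float)
        cfg = nets.LossConfig(dice_weight=0.0, focal_weight=1.0, focal_gamma=0.0, focal_alpha=0.5)
        loss = nets.dice_focal_loss(p, t, cfg)
        bce = -(t * np.log(p) + (1 - t) * np.log(1 - p)).mean()
        assert loss == pytest.approx(0.5 * bce, abs=1e-9)

    def test_invalid_voxels_contribute_exactly_nothing(self):
        rng = np.random.default_rng(9)
        values = rng.uniform(size=(6, 6, 6)).astype(np.float32)
        invalid = rng.uniform(size=(6, 6, 6)) > 0.8
        values[invalid] = 0.0
        target = HeatmapTarget(
            values=values, invalid_mask=invalid, landmark_index=np.array([3.0, 3.0, 3.0])
        )
        p = rng.uniform(0.1, 0.9, (6, 6, 6))
        base = nets.dice_focal_loss(p, target)
        p2 = p.copy()
        p2[invalid] = rng.uniform(size=int(invalid.sum()))
        assert abs(nets.dice_focal_loss(p2, target) - base) <= 1e-12

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError, match="mismatch"):
            nets.dice_focal_loss(np.zeros((4, 4, 4)), np.zeros((5, 4, 4)))

    def test_non_negative(self):
        rng = np.random.default_rng(10)
        for _ in range(10):
            p = rng.uniform(0, 1, (5, 5, 5))
            t = rng.uniform(0, 1, (5, 5, 5))
            assert nets.dice_focal_loss(p, t) >= 0.0

    def test_invalid_loss_config_rejected(self):
        with pytest.raises(ValueError):
            nets.LossConfig(dice_weight=0.0, focal_weight=0.0)


class TestTrain:
    def _tiny_heatmap_problem(self, n=4, shape=(8, 8, 4)):
        from aclloc.targets import gaussian_heatmap
        from aclloc.volio import Geometry

        rng = np.random.default_rng(11)
        geom = Geometry(spacing=(1, 1, 1), origin=(0, 0, 0))
        data = []
        for _ in range(n):
            lm = rng.uniform(2, np.array(shape) - 2)
            hm = gaussian_heatmap(geom, shape, lm, sigma=1.5)
            x = hm.values + rng.normal(0, 0.05, shape).astype(np.float32)
            data.append((x.astype(np.float32), hm))
        return data

    def test_lr_zero_keeps_weights(self):
        cfg = nets.NetConfig(depth=2, base_channels=2, input_shape=(8, 8, 4))
        model = nets.build_heatmap_net(cfg, seed=12)
        before = [p.value.copy() for p in model.params()]
        _, history = nets.train(
            model, self._tiny_heatmap_problem(), nets.TrainConfig(epochs=1, lr=0.0, seed=0)
        )
        assert len(history) == 1
        for p, b in zip(model.params(), before):
            np.testing.assert_array_equal(p.value, b)

    def test_seeded_determinism(self):
        data = self._tiny_heatmap_problem()
        hists = []
        for _ in range(2):
            cfg = nets.NetConfig(depth=2, base_channels=2, input_shape=(8, 8, 4))
            model = nets.build_heatmap_net(cfg, seed=13)
            _, history = nets.train(model, data, nets.TrainConfig(epochs=3, lr=0.05, seed=13))
            hists.append(history)
        assert hists[0] == hists[1]

    def test_loss_decreases_on_phantom_fixture(self, small_spec):
        """Scaled-down heatmap training cuts the loss by well over 20%."""
        from aclloc.phantom import make_dataset
        from aclloc.pipeline import heatmap_training_set

        cases = make_dataset(10, small_spec, seed=31)
        dataset = heatmap_training_set(cases, roi_shape=(24, 24, 8))
        cfg = nets.NetConfig(depth=3, base_channels=8, input_shape=(24, 24, 8))
        model = nets.build_heatmap_net(cfg, seed=31)
        _, history = nets.train(model, dataset, nets.TrainConfig(epochs=12, lr=0.05, seed=31))
        assert history[-1] < 0.8 * history[0]
        # smoothed trajectory is decreasing overall (not necessarily per-epoch)
        smoothed = np.convolve(history, np.ones(3) / 3, mode="valid")
        assert smoothed[-1] < smoothed[0]

    def test_empty_dataset_rejected(self):
        cfg = nets.NetConfig(depth=1, base_channels=2, input_shape=(4, 4, 4))
        with pytest.raises(ValueError):
            nets.train(nets.build_heatmap_net(cfg), [], nets.TrainConfig(epochs=1))


class TestCheckpoint:
    def test_round_trip(self, tmp_path):
        cfg = nets.NetConfig(depth=2, base_channels=2, input_shape=(8, 8, 4))
        model = nets.build_heatmap_net(cfg, seed=14)
        x = np.random.default_rng(5).normal(size=(8, 8, 4)).astype(np.float32)
        expected = model.forward(x)
        path = tmp_path / "ckpt.npz"
        nets.save_checkpoint(model, path)
        back = nets.load_checkpoint(path)
        np.testing.assert_array_equal(back.forward(x), expected)
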