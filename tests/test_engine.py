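"""Streamed forward/backward vs the naive full-image oracle; skipping; CAM."""

import numpy as np
import pytest

import slidestream as ss
from slidestream.engine import EngineError, NoContentError, naive_cam
from slidestream.nn import Conv2D, ReLU, StreamableNet


def _tile_for(net, target=32):
    s = net.stride
    return s * max(1, target // s)


def _random_case(seed, size=None):
    rng = np.random.default_rng(seed)
    net = ss.random_net(rng, depth=int(rng.integers(2, 5)), channels=4)
    size = size or int(rng.integers(48, 128))
    img = ss.TiledImage(rng.integers(0, 255, (size, size + 7, 3), dtype=np.uint8))
    return net, img


class TestForwardStreamed:
    def test_single_tile_equals_naive_exactly(self):
        net, img = _random_case(0, 64)
        patches = ss.plan_patches(img, _tile_for(net, 256), net.geometries())
        assert patches.n_tiles == 1
        rec = ss.forward_streamed(net, img, patches)
        logit, _ = ss.naive_reference(net, img)
        assert rec.logit == logit

    @pytest.mark.parametrize("seed", range(6))
    def test_multi_tile_logit_matches_naive(self, seed):
        net, img = _random_case(seed)
        patches = ss.plan_patches(img, _tile_for(net), net.geometries())
        rec = ss.forward_streamed(net, img, patches)
        logit, _ = ss.naive_reference(net, img)
        assert abs(rec.logit - logit) <= 1e-5 * max(1.0, abs(logit))
        assert rec.peak_activation_area <= (patches.tile_size + 2 * patches.halo) ** 2

    def test_argmax_tie_breaks_row_major_across_tiles(self):
        # two identical bright pixels; the earlier one in row-major order wins
        net = StreamableNet(
            [Conv2D(np.ones((1, 3, 1, 1)) / 3.0, np.zeros(1), 1, 0)], np.ones(1), 0.0
        )
        arr = np.zeros((8, 8, 3), dtype=np.uint8)
        arr[1, 6] = 200  # in the second tile (cols 4-8), earlier row
        arr[5, 1] = 200  # in the first tile, later row
        img = ss.TiledImage(arr)
        patches = ss.plan_patches(img, 4, net.geometries())
        rec = ss.forward_streamed(net, img, patches)
        assert tuple(rec.argmax[0]) == (1, 6)

    def test_all_white_with_skip_raises_no_content(self):
        net, _ = _random_case(1)
        img = ss.TiledImage(np.full((40, 40, 3), 255, np.uint8))
        patches = ss.plan_patches(img, _tile_for(net), net.geometries())
        with pytest.raises(NoContentError):
            ss.forward_streamed(net, img, patches, skip_white=True)

    def test_pipelined_scheduler_is_bit_identical(self):
        net, img = _random_case(2)
        plan = ss.sample_plan(3)
        patches = ss.plan_patches(img, _tile_for(net), net.geometries())
        a = ss.forward_streamed(net, img, patches, plan=plan, skip_white=True)
        b = ss.forward_streamed(net, img, patches, plan=plan, skip_white=True, pipeline=True)
        assert a.logit == b.logit
        assert np.array_equal(a.maxima, b.maxima)
        assert np.array_equal(a.argmax, b.argmax)


class TestBackwardStreamed:
    @pytest.mark.parametrize("seed", range(6))
    def test_gradients_match_naive_autodiff(self, seed):
        net, img = _random_case(seed + 10)
        patches = ss.plan_patches(img, _tile_for(net), net.geometries())
        rec = ss.forward_streamed(net, img, patches)
        gs = ss.backward_streamed(net, img, patches, rec, 0.37)
        _, gref = ss.naive_reference(net, img, dloss_dlogit=0.37)
        assert gs.max_rel_error(gref) <= 1e-4

    def test_single_bright_region_recomputes_one_patch(self):
        rng = np.random.default_rng(3)
        net = StreamableNet(
            [Conv2D(rng.uniform(0.1, 0.5, (3, 3, 3, 3)), np.zeros(3), 1, 1), ReLU()],
            rng.uniform(0.5, 1.0, 3), 0.0,
        )
        arr = np.zeros((64, 64, 3), dtype=np.uint8)
        arr[40:44, 40:44] = 255  # single bright region in one tile
        img = ss.TiledImage(arr)
        patches = ss.plan_patches(img, 32, net.geometries())
        rec = ss.forward_streamed(net, img, patches)
        gs = ss.backward_streamed(net, img, patches, rec, 1.0)
        assert gs.recomputed_patches == 1
        _, gref = ss.naive_reference(net, img)
        assert gs.max_rel_error(gref) <= 1e-4

    def test_zero_upstream_gradient_short_circuits(self):
        net, img = _random_case(4)
        patches = ss.plan_patches(img, _tile_for(net), net.geometries())
        rec = ss.forward_streamed(net, img, patches)
        gs = ss.backward_streamed(net, img, patches, rec, 0.0)
        assert gs.recomputed_patches == 0
        assert all(np.all(v == 0) for v in gs.grads.values())

    def test_record_mismatch_rejected(self):
        net, img = _random_case(5)
        patches = ss.plan_patches(img, _tile_for(net), net.geometries())
        rec = ss.forward_streamed(net, img, patches, plan=ss.sample_plan(1))
        with pytest.raises(EngineError):
            ss.backward_streamed(net, img, patches, rec, 1.0, plan=ss.sample_plan(2))

    def test_recompute_counter_equals_argmax_patch_count(self):
        net, img = _random_case(6)
        patches = ss.plan_patches(img, _tile_for(net), net.geometries())
        rec = ss.forward_streamed(net, img, patches)
        gs = ss.backward_streamed(net, img, patches, rec, 1.0)
        s, t = patches.stride, patches.tile_size
        tiles = {((r * s) // t, (c * s) // t) for r, c in rec.argmax}
        assert gs.recomputed_patches == len(tiles)


def _skip_sound_fixture(seed=7):
    """Net whose all-white response is exactly zero after ReLU, and an image
    with one interior tile (plus halo) of pure white."""
    rng = np.random.default_rng(seed)
    w1 = rng.normal(0, 0.3, (4, 3, 3, 3))
    b1 = -w1.sum(axis=(1, 2, 3))  # cancels the all-ones response
    w2 = rng.normal(0, 0.3, (4, 4, 3, 3))
    b2 = -np.abs(rng.normal(0, 0.05, 4))
    net = StreamableNet(
        [Conv2D(w1, b1, 1, 1), ReLU(), Conv2D(w2, b2, 1, 1), ReLU()],
        rng.uniform(0.2, 1.0, 4), 0.1,
    )
    arr = rng.integers(0, 256, (96, 96, 3), dtype=np.uint8)
    m = ss.halo_margin(net.geometries())
    arr[32 - m : 64 + m, 32 - m : 64 + m] = 255  # tile [32,64)^2 white incl. halo
    return net, ss.TiledImage(arr)


class TestSkipping:
    def test_skip_changes_nothing_when_white_wins_no_channel(self):
        net, img = _skip_sound_fixture()
        patches = ss.plan_patches(img, 32, net.geometries())
        on = ss.forward_streamed(net, img, patches, skip_white=True)
        off = ss.forward_streamed(net, img, patches, skip_white=False)
        assert on.n_skipped >= 1
        assert on.white_win_channels == []
        assert on.logit == off.logit
        assert np.array_equal(on.argmax, off.argmax)
        g_on = ss.backward_streamed(net, img, patches, on, 0.9)
        g_off = ss.backward_streamed(net, img, patches, off, 0.9)
        assert g_on.max_rel_error(g_off) == 0.0

    def test_deviation_flag_fires_when_white_would_win(self):
        # a net with positive response to white: skipped patches would have won
        rng = np.random.default_rng(8)
        net = ss.random_net(rng, depth=3, channels=4)
        arr = np.full((128, 128, 3), 255, np.uint8)
        arr[10:50, 10:50] = rng.integers(0, 200, (40, 40, 3), dtype=np.uint8)
        img = ss.TiledImage(arr)
        patches = ss.plan_patches(img, _tile_for(net), net.geometries())
        rec = ss.forward_streamed(net, img, patches, skip_white=True)
        assert rec.n_skipped > 0
        assert len(rec.white_win_channels) > 0


class TestMemoryContract:
    def test_peak_activation_area_independent_of_canvas(self):
        net = ss.demo_net(np.random.default_rng(0))
        content = np.random.default_rng(1).integers(0, 200, (128, 128, 3), dtype=np.uint8)
        peaks = []
        for canvas in (512, 2048, 8192):
            big = ss.TiledImage(content, canvas_shape=(canvas, canvas), origin=(64, 64))
            patches = ss.plan_patches(big, 64, net.geometries())
            rec = ss.forward_streamed(net, big, patches, skip_white=True)
            assert rec.peak_activation_area <= (64 + 2 * patches.halo) ** 2
            peaks.append(rec.peak_activation_area)
        assert len(set(peaks)) == 1

    def test_skipping_yield_on_mostly_white_canvas(self):
        net = ss.demo_net(np.random.default_rng(0))
        content = np.random.default_rng(1).integers(0, 200, (256, 256, 3), dtype=np.uint8)
        big = ss.TiledImage(content, canvas_shape=(1024, 1024), origin=(0, 0))
        patches = ss.plan_patches(big, 64, net.geometries())
        rec = ss.forward_streamed(net, big, patches, skip_white=True)
        # >= 75% of the canvas is padding; >= 70% of patches must be skipped
        assert rec.n_skipped / patches.n_tiles >= 0.70


class TestCam:
    def test_stitched_cam_matches_naive(self):
        net, img = _random_case(20)
        patches = ss.plan_patches(img, _tile_for(net), net.geometries())
        cam = ss.cam_streamed(net, img, patches)
        ref = naive_cam(net, img)
        assert cam.shape == ref.shape
        assert np.abs(cam - ref).max() <= 1e-6

    def test_zero_weights_give_constant_sigmoid_of_bias(self):
        net, img = _random_case(21)
        net.head_w[:] = 0.0
        net.head_b = 0.3
        patches = ss.plan_patches(img, _tile_for(net), net.geometries())
        cam = ss.cam_streamed(net, img, patches)
        assert np.allclose(cam, 1.0 / (1.0 + np.exp(-0.3)))

    def test_cam_values_in_unit_interval(self):
        net, img = _random_case(22)
        patches = ss.plan_patches(img, _tile_for(net), net.geometries())
        cam = ss.cam_streamed(net, img, patches)
        assert cam.min() >= 0.0 and cam.max() <= 1.0


class TestTrainStep:
    def test_identity_transition_reduces_to_bce(self):
        net, img = _random_case(30)
        step = ss.train_step(net, img, 1, tile_size=_tile_for(net), skip_white=False)
        logit, _ = ss.naive_reference(net, img)
        p = 1.0 / (1.0 + np.exp(-logit))
        assert np.isclose(step.loss, -np.log(p), atol=1e-9)

    def test_same_seed_gives_identical_trajectories(self, tiny_study):
        samples = [(s.image, s.label) for s in tiny_study.slides]
        runs = []
        for _ in range(2):
            net = ss.demo_net(np.random.default_rng(0))
            h = ss.train_classifier(net, samples, epochs=2, seed=5, tile_size=128)
            runs.append(h.epoch_losses)
        assert runs[0] == runs[1]

    def test_loss_decreases_over_repeated_steps(self, tiny_study):
        pos = next(s for s in tiny_study.slides if s.label == 1)
        neg = next(s for s in tiny_study.slides if s.label == 0)
        net = ss.demo_net(np.random.default_rng(0))
        opt = ss.AdamW(lr=1e-3)
        losses = []
        for _ in range(25):
            l1 = ss.train_step(net, pos.image, 1, optimizer=opt, tile_size=128).loss
            l2 = ss.train_step(net, neg.image, 0, optimizer=opt, tile_size=128).loss
            losses.append(l1 + l2)
        assert np.mean(losses[-5:]) < np.mean(losses[:5])

    def test_invalid_label_rejected(self, tiny_study):
        net = ss.demo_net(np.random.default_rng(0))
        with pytest.raises(EngineError):
            ss.train_step(net, tiny_study.slides[0].image, 2, tile_size=128)
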