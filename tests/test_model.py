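"""Two-stream scoring core: softmax geometry, Hadamard aggregation, loss."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from toothmark.model import (
    GridMapping,
    RegionScoringHead,
    ToothMarkNet,
    bce_loss,
    image_score,
    map_box_to_grid,
    predict_image,
    select_boxes,
    softmax_over_classes,
    softmax_over_regions,
    spp_pool,
)
from toothmark.srp import CandidateRegion


from .oracles import oracle_image_score


class TestGridMapping:
    def test_aligned_box_covers_single_cell(self):
        assert map_box_to_grid((0, 0, 32, 32), GridMapping()) == (0, 0, 1, 1)

    def test_offset_box_covers_two_by_two(self):
        assert map_box_to_grid((16, 16, 32, 32), GridMapping()) == (0, 0, 2, 2)

    def test_corner_box_clips_to_grid(self):
        assert map_box_to_grid((208, 208, 16, 16), GridMapping()) == (6, 6, 7, 7)

    def test_exhaustive_32px_boxes_cover_one_to_two_cells(self):
        gm = GridMapping()
        extents = set()
        for x in range(0, 193):
            i0, _, i1, _ = map_box_to_grid((x, 0, 32, 32), gm)
            extents.add(i1 - i0)
        assert extents == {1, 2}

    def test_invalid_stride_combination_rejected(self):
        with pytest.raises(ValueError):
            GridMapping(input_size=225)


class TestSppPool:
    def test_single_cell_region_returns_cell_vector_everywhere(self, rng):
        fmap = rng.random((8, 7, 7)).astype(np.float32)
        out = spp_pool(fmap, (3, 2, 4, 3), levels=(1, 2))
        assert out.shape == (5 * 8,)
        for b in range(5):
            assert (out[b * 8 : (b + 1) * 8] == fmap[:, 2, 3]).all()

    def test_constant_feature_map_pools_constant(self):
        fmap = np.full((4, 7, 7), 3.25, np.float32)
        a = spp_pool(fmap, (0, 0, 2, 2))
        b = spp_pool(fmap, (5, 5, 7, 7))
        assert (a == 3.25).all() and (a == b).all()

    def test_two_by_two_region_bins_are_cells_plus_global_max(self, rng):
        fmap = rng.random((16, 7, 7)).astype(np.float32)
        out = spp_pool(fmap, (2, 3, 4, 5), levels=(1, 2))
        C = 16
        cells = fmap[:, 3:5, 2:4]
        assert np.allclose(out[:C], cells.max(axis=(1, 2)))
        expected = [cells[:, 0, 0], cells[:, 0, 1], cells[:, 1, 0], cells[:, 1, 1]]
        for b, cell in enumerate(expected):
            assert (out[(b + 1) * C : (b + 2) * C] == cell).all()


class TestStreams:
    def test_zero_logits_give_uniform_streams(self):
        zc = np.zeros((2, 3))
        assert np.allclose(softmax_over_classes(zc), 0.5)
        zd = np.zeros((2, 4))
        assert np.allclose(softmax_over_regions(zd), 0.25)

    def test_closed_form_columns_and_rows(self):
        col = softmax_over_classes(np.array([[math.log(3.0)], [0.0]]))
        assert np.allclose(col[:, 0], [0.75, 0.25])
        row = softmax_over_regions(np.array([[math.log(2.0), 0.0, 0.0]]))
        assert np.allclose(row[0], [0.5, 0.25, 0.25])

    def test_single_region_detection_stream_is_one(self, rng):
        sd = softmax_over_regions(rng.normal(size=(2, 1)))
        assert np.allclose(sd, 1.0)

    @settings(max_examples=50, deadline=None)
    @given(st.integers(0, 10_000), st.integers(1, 30))
    def test_normalisation_and_score_bounds_random(self, seed, R):
        rng = np.random.default_rng(seed)
        xc = rng.normal(scale=3, size=(2, R))
        xd = rng.normal(scale=3, size=(2, R))
        sc, sd = softmax_over_classes(xc), softmax_over_regions(xd)
        assert np.allclose(sc.sum(axis=0), 1.0, atol=1e-6)
        assert np.allclose(sd.sum(axis=1), 1.0, atol=1e-6)
        y = image_score(sc, sd)
        assert ((y > 0) & (y < 1)).all()
        assert (y <= sc.max(axis=1) + 1e-12).all()
        assert np.allclose(y, oracle_image_score(xc, xd), atol=1e-6)


class TestImageScore:
    def test_uniform_streams(self):
        y = image_score(np.full((2, 2), 0.5), np.full((2, 2), 0.5))
        assert np.allclose(y, [0.5, 0.5])

    def test_single_region_score_equals_class_stream(self, rng):
        sc = softmax_over_classes(rng.normal(size=(2, 1)))
        y = image_score(sc, np.ones((2, 1)))
        assert np.allclose(y, sc[:, 0])

    def test_hand_computed_hadamard_sum(self):
        sc = np.full((2, 2), 0.5)
        sd = np.array([[0.9, 0.1], [0.2, 0.8]])
        assert np.allclose(image_score(sc, sd), [0.5, 0.5])

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            image_score(np.ones((2, 3)), np.ones((2, 4)))


class TestLossAndPrediction:
    def test_uniform_score_loss_closed_form(self):
        assert bce_loss(np.array([0.5, 0.5]), 1) == pytest.approx(2 * math.log(2))

    def test_perfect_prediction_limit(self):
        assert bce_loss(np.array([1e-9, 1 - 1e-9]), 1) == pytest.approx(0.0, abs=1e-6)

    def test_monotone_in_correct_class_score(self):
        losses = [bce_loss(np.array([0.3, y1]), 1) for y1 in (0.2, 0.5, 0.8)]
        assert losses[0] > losses[1] > losses[2]

    def test_argmax_and_tie_rule(self):
        assert predict_image(np.array([0.2, 0.7])) == 1
        assert predict_image(np.array([0.5, 0.5])) == 0
        assert predict_image(np.array([0.4, 0.8])) == predict_image(np.array([0.2, 0.4]))


class TestSelectBoxes:
    def _regions(self, n):
        return [CandidateRegion(10 * i, 0, 8, 8) for i in range(n)]

    def test_uniform_detection_row_selects_nothing(self):
        sd = np.full((2, 4), 0.25)
        assert select_boxes(sd, self._regions(4)) == []

    def test_threshold_arithmetic(self):
        sd = np.array([[0.25, 0.25, 0.25, 0.25], [0.7, 0.1, 0.1, 0.1]])
        picked = select_boxes(sd, self._regions(4), target_class=1)
        assert len(picked) == 1
        assert picked[0][0].x_min == 0 and picked[0][1] == pytest.approx(0.7)

    def test_selected_count_bounded_and_sorted(self, rng):
        sd = softmax_over_regions(rng.normal(size=(2, 9)))
        picked = select_boxes(sd, self._regions(9))
        assert len(picked) <= 9
        scores = [s for _, s in picked]
        assert scores == sorted(scores, reverse=True)


class TestNetworkContracts:
    def test_embeddings_nonnegative_and_shape_invariant(self, rng):
        head = RegionScoringHead(d_spp=5 * 8, embed_dim=64, rng=rng)
        gm = GridMapping(feature_channels=8)
        fmap = rng.normal(size=(8, 7, 7)).astype(np.float32)
        for R in (1, 7, 30):
            regions = [
                CandidateRegion(int(rng.integers(0, 192)), int(rng.integers(0, 192)), 32, 32)
                for _ in range(R)
            ]
            out = head.forward(fmap, regions, gm)
            assert out["emb"].shape == (R, 64)
            assert (out["emb"] >= 0).all()
            assert out["sigma_class"].shape == (2, R)
            assert ((out["y"] > 0) & (out["y"] < 1)).all()

    def test_default_embedding_width_is_4096(self):
        head = RegionScoringHead(d_spp=40)
        assert head.fc2.out_features == 4096

    def test_tiny_backbone_feature_shape(self, rng):
        net = ToothMarkNet(arch="tiny_test", feature_channels_override=12, embed_dim=32)
        x = rng.random((2, 3, 224, 224)).astype(np.float32)
        fmap = net.backbone.forward(x)
        assert fmap.shape == (2, 12, 7, 7)
        assert np.isfinite(fmap).all()

    def test_zero_image_forward_is_finite(self):
        net = ToothMarkNet(arch="tiny_test", feature_channels_override=8, embed_dim=16)
        out = net.forward(
            np.zeros((1, 3, 224, 224), np.float32), [[CandidateRegion(0, 0, 32, 32)]]
        )[0]
        assert np.isfinite(out["y"]).all()

    def test_both_streams_receive_gradient(self, rng):
        net = ToothMarkNet(arch="tiny_test", feature_channels_override=8, embed_dim=16, seed=5)
        img = rng.random((1, 3, 224, 224)).astype(np.float32)
        regions = [CandidateRegion(30, 40, 32, 32), CandidateRegion(100, 100, 32, 32)]
        net.train_batch(img, [regions], np.array([1]))
        gc = np.abs(net.head.head_class.weight.grad).sum()
        gd = np.abs(net.head.head_det.weight.grad).sum()
        assert gc > 0 and gd > 0

    def test_checkpoint_round_trip(self, tmp_path, rng):
        net = ToothMarkNet(arch="tiny_test", feature_channels_override=8, embed_dim=16, seed=9)
        path = tmp_path / "model.npz"
        net.save(path)
        net2 = ToothMarkNet.load(path)
        img = rng.random((1, 3, 224, 224)).astype(np.float32)
        regions = [[CandidateRegion(60, 60, 32, 32)]]
        y1 = net.forward(img, regions)[0]["y"]
        y2 = net2.forward(img, regions)[0]["y"]
        assert np.allclose(y1, y2)
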