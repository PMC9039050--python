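"""Mask rasterization, AND-masking, resizing and augmentation contracts."""

import json

import numpy as np
import pytest
from PIL import Image

from toothmark.preprocess import (
    PreprocessConfig,
    TongueSample,
    apply_mask,
    augment,
    augment_pair,
    load_manifest,
    load_mask,
    rasterize_polygons,
    resize_to_input,
)


class TestLoadMask:
    def test_full_frame_rectangle_covers_canvas(self, tmp_path):
        ann = {
            "imageHeight": 10,
            "imageWidth": 10,
            "shapes": [{"points": [[0, 0], [9, 0], [9, 9], [0, 9]]}],
        }
        p = tmp_path / "mask.json"
        p.write_text(json.dumps(ann))
        mask = load_mask(p)
        assert mask.shape == (10, 10)
        assert mask.all()

    def test_empty_polygon_list_rejected(self, tmp_path):
        p = tmp_path / "mask.json"
        p.write_text(json.dumps({"imageHeight": 10, "imageWidth": 10, "shapes": []}))
        with pytest.raises(ValueError):
            load_mask(p)

    def test_degenerate_polygon_rejected(self):
        with pytest.raises(ValueError, match="3 vertices"):
            rasterize_polygons([[(0, 0), (5, 5)]], (10, 10))

    def test_triangle_interior_and_exterior(self):
        """Strict interior pixels are 1, strict exterior pixels 0.

        Compared against a brute-force point-in-polygon test per pixel
        center, ignoring the half-pixel band around the edges where
        rasterization conventions legitimately differ.
        """
        tri = [(0.0, 0.0), (9.0, 0.0), (0.0, 9.0)]
        mask = rasterize_polygons([tri], (10, 10))
        for y in range(10):
            for x in range(10):
                # signed position relative to the hypotenuse x + y = 9
                d = x + y - 9
                if d < -1:  # strictly inside
                    assert mask[y, x] == 1, (x, y)
                elif d > 1:  # strictly outside
                    assert mask[y, x] == 0, (x, y)
        assert mask[9, 9] == 0

    def test_raster_mask_thresholds_any_positive_value(self, tmp_path):
        arr = np.zeros((6, 6), dtype=np.uint8)
        arr[2:4, 2:4] = 1  # 1-bit style, not 255
        p = tmp_path / "m.png"
        Image.fromarray(arr).save(p)
        assert (load_mask(p) == (arr > 0)).all()


class TestApplyMask:
    def test_all_ones_identity_and_all_zeros_annihilate(self, rng):
        img = rng.integers(0, 256, (8, 9, 3), dtype=np.uint8)
        assert (apply_mask(img, np.ones((8, 9), np.uint8)) == img).all()
        assert not apply_mask(img, np.zeros((8, 9), np.uint8)).any()

    def test_single_pixel_mask(self):
        img = np.full((8, 8, 3), 100, np.uint8)
        mask = np.zeros((8, 8), np.uint8)
        mask[3, 4] = 1
        out = apply_mask(img, mask)
        assert (out[3, 4] == 100).all()
        assert out.sum() == 300

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError, match="disagree"):
            apply_mask(np.zeros((4, 4, 3), np.uint8), np.zeros((5, 4), np.uint8))

    def test_idempotent_and_matches_per_pixel_oracle(self, rng):
        img = rng.integers(0, 256, (16, 16, 3), dtype=np.uint8)
        mask = (rng.random((16, 16)) < 0.5).astype(np.uint8)
        out = apply_mask(img, mask)
        assert (apply_mask(out, mask) == out).all()
        for y in range(16):
            for x in range(16):
                expected = img[y, x] if mask[y, x] else (0, 0, 0)
                assert (out[y, x] == expected).all()


class TestResize:
    def test_noop_and_constancy(self):
        img = np.full((224, 224, 3), 7, np.uint8)
        assert resize_to_input(img, 224) is img
        big = np.full((448, 448, 3), 7, np.uint8)
        out = resize_to_input(big, 224)
        assert out.shape == (224, 224, 3)
        assert (out == 7).all()

    def test_aspect_ratio_not_preserved(self):
        out = resize_to_input(np.zeros((100, 200, 3), np.uint8), 224)
        assert out.shape == (224, 224, 3)

    def test_zero_area_rejected(self):
        with pytest.raises(ValueError):
            resize_to_input(np.zeros((0, 5, 3), np.uint8), 224)


class TestAugment:
    def test_all_probabilities_zero_is_identity(self, rng):
        cfg = PreprocessConfig(rotation_max_deg=0, hflip_prob=0, vflip_prob=0)
        img = rng.integers(0, 256, (224, 224, 3), dtype=np.uint8)
        assert (augment(img, cfg, rng) == img).all()

    def test_hflip_is_an_involution(self, rng):
        cfg = PreprocessConfig(rotation_max_deg=0, hflip_prob=1.0, vflip_prob=0)
        img = rng.integers(0, 256, (224, 224, 3), dtype=np.uint8)
        once = augment(img, cfg, np.random.default_rng(0))
        twice = augment(once, cfg, np.random.default_rng(0))
        assert (twice == img).all()

    def test_deterministic_given_rng_state(self, rng):
        cfg = PreprocessConfig()
        img = rng.integers(0, 256, (224, 224, 3), dtype=np.uint8)
        a = augment(img, cfg, np.random.default_rng(77))
        b = augment(img, cfg, np.random.default_rng(77))
        assert (a == b).all()

    def test_pair_keeps_background_exactly_zero(self, rng):
        cfg = PreprocessConfig(rotation_max_deg=15, hflip_prob=0.5, vflip_prob=0.5)
        mask = np.zeros((224, 224), np.uint8)
        mask[60:160, 70:150] = 1
        img = (rng.integers(100, 256, (224, 224, 3))).astype(np.uint8) * mask[..., None]
        out_img, out_mask = augment_pair(img, mask, cfg, np.random.default_rng(3))
        assert not out_img[out_mask == 0].any()


class TestManifest:
    def test_round_trip_with_generator(self, tmp_path):
        from toothmark.synthetic import generate_dataset

        manifest = generate_dataset(3, 4, seed=5, outdir=tmp_path)
        samples = load_manifest(manifest)
        assert len(samples) == 7
        assert sum(s.label for s in samples) == 3
        loaded = samples[0].load()
        assert loaded.image.shape[:2] == loaded.mask.shape
        assert samples[0].truth_boxes  # positives carry ground truth

    def test_bad_label_names_row(self, tmp_path):
        p = tmp_path / "m.csv"
        p.write_text("image,mask,label\na.png,b.png,0\nc.png,d.png,2\n")
        with pytest.raises(ValueError, match="row 3"):
            load_manifest(p)

    def test_missing_column_rejected(self, tmp_path):
        p = tmp_path / "m.csv"
        p.write_text("image,label\na.png,0\n")
        with pytest.raises(ValueError, match="mask"):
            load_manifest(p)

    def test_label_outside_binary_rejected_in_sample(self):
        with pytest.raises(ValueError):
            TongueSample(label=2)
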