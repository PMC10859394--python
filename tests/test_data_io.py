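"""Annotation conversion, preprocessing and splitting."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from cowseg.data_io import (
    DatasetManifest,
    ImageSample,
    ManifestRecord,
    labelme_to_mask,
    load_mask,
    preprocess_frame,
    rasterize_polygon,
    save_mask,
    split_dataset,
    to_uint8_labels,
)


def point_in_polygon_evenodd(px, py, pts):
    """Independent scalar even-odd crossing test (the oracle)."""
    crossings = 0
    n = len(pts)
    for i in range(n):
        x1, y1 = pts[i]
        x2, y2 = pts[(i + 1) % n]
        if (y1 > py) != (y2 > py):
            xint = x1 + (py - y1) * (x2 - x1) / (y2 - y1)
            if px < xint:
                crossings += 1
    return crossings % 2 == 1


class TestRasterize:
    def test_axis_aligned_square_100_pixels(self):
        # square covering pixel centers 0..9 in both axes
        pts = [(-0.5, -0.5), (9.5, -0.5), (9.5, 9.5), (-0.5, 9.5)]
        mask = rasterize_polygon(np.array(pts), (20, 20))
        assert mask.sum() == 100
        assert mask[:10, :10].all()

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.integers(3, 7), st.integers(1, 1000))
    def test_matches_brute_force_oracle(self, n_verts, seed):
        r = np.random.default_rng(seed)
        pts = r.uniform(-2, 30, size=(n_verts, 2))
        mask = rasterize_polygon(pts, (32, 32))
        for py in range(0, 32, 3):
            for px in range(0, 32, 3):
                assert mask[py, px] == point_in_polygon_evenodd(px, py, pts)

    def test_degenerate_polygon_rejected(self):
        with pytest.raises(ValueError):
            rasterize_polygon(np.array([(0, 0), (1, 1)]), (8, 8))


class TestLabelmeToMask:
    def test_empty_shapes_all_zero(self):
        doc = {"shapes": [], "imageHeight": 6, "imageWidth": 7}
        mask = labelme_to_mask(doc, {"cow": 1})
        assert mask.shape == (6, 7) and mask.dtype == np.uint8
        assert not mask.any()

    def test_two_disjoint_classes_counts(self):
        sq = lambda x0, y0, s: [(x0 - 0.5, y0 - 0.5), (x0 + s - 0.5, y0 - 0.5),
                                (x0 + s - 0.5, y0 + s - 0.5), (x0 - 0.5, y0 + s - 0.5)]
        doc = {"shapes": [
            {"label": "back", "points": sq(1, 1, 3)},
            {"label": "body", "points": sq(10, 10, 4)},
        ], "imageHeight": 20, "imageWidth": 20}
        mask = labelme_to_mask(doc, {"back": 1, "body": 2})
        assert (mask == 1).sum() == 9
        assert (mask == 2).sum() == 16

    def test_later_polygon_overwrites(self):
        sq = [(-0.5, -0.5), (4.5, -0.5), (4.5, 4.5), (-0.5, 4.5)]
        doc = {"shapes": [{"label": "a", "points": sq},
                          {"label": "b", "points": sq}],
               "imageHeight": 6, "imageWidth": 6}
        mask = labelme_to_mask(doc, {"a": 1, "b": 2})
        assert (mask == 1).sum() == 0 and (mask == 2).sum() == 25

    def test_unknown_class_named_in_error(self):
        doc = {"shapes": [{"label": "horse", "points": [(0, 0), (3, 0), (0, 3)]}],
               "imageHeight": 5, "imageWidth": 5}
        with pytest.raises(KeyError, match="horse"):
            labelme_to_mask(doc, {"cow": 1})

    def test_malformed_polygon_names_shape_index(self):
        doc = {"shapes": [{"label": "cow", "points": [(0, 0), (1, 1)]}],
               "imageHeight": 5, "imageWidth": 5}
        with pytest.raises(ValueError, match="shape 0"):
            labelme_to_mask(doc, {"cow": 1})


class TestLabelCast:
    def test_value_preserving_not_rescaling(self):
        m16 = np.array([[0, 1], [2, 255]], dtype=np.uint16)
        out = to_uint8_labels(m16)
        assert out.dtype == np.uint8
        np.testing.assert_array_equal(out, m16)

    def test_overflow_rejected(self):
        with pytest.raises(ValueError):
            to_uint8_labels(np.array([[300]], dtype=np.uint16))


class TestPreprocessFrame:
    def test_capture_resolution_to_network_size(self):
        frame = np.zeros((2160, 3840, 3), dtype=np.uint8)
        out, info = preprocess_frame(frame)
        assert out.shape == (704, 1216, 3)
        assert info["scale"] == pytest.approx(1216 / 3840)

    def test_identity_when_already_target(self):
        frame = np.full((704, 1216, 3), 7, dtype=np.uint8)
        out, info = preprocess_frame(frame)
        assert out is frame and info["scale"] == 1.0

    def test_mask_stays_binary(self):
        mask = (np.random.default_rng(0).random((2160, 3840)) > 0.5).astype(np.uint8)
        out, _ = preprocess_frame(mask, is_mask=True)
        assert out.shape == (704, 1216)
        assert set(np.unique(out)) <= {0, 1}

    def test_degenerate_input_rejected(self):
        with pytest.raises(ValueError):
            preprocess_frame(np.zeros((0, 5, 3)))


class TestMaskRoundTrip:
    def test_indexed_png_lossless(self, tmp_path, rng):
        mask = rng.integers(0, 3, (40, 60)).astype(np.uint8)
        save_mask(mask, tmp_path / "m.png")
        np.testing.assert_array_equal(load_mask(tmp_path / "m.png"), mask)


def _dummy_manifest(n_per_view):
    recs = [ManifestRecord(id=f"c{i:03d}", view=v, image_path=f"c{i:03d}_{v}.png")
            for i in range(n_per_view) for v in ("top", "back")]
    return DatasetManifest(recs)


class TestSplit:
    def test_eighty_twenty_counts(self):
        man = _dummy_manifest(550)
        train, test = split_dataset(man, (0.8, 0.2), seed=0)
        assert len(train.by_view("top")) == 440
        assert len(test.by_view("top")) == 110

    def test_partition_and_determinism(self):
        man = _dummy_manifest(20)
        t1, e1 = split_dataset(man, (0.8, 0.2), seed=3)
        t2, e2 = split_dataset(man, (0.8, 0.2), seed=3)
        key = lambda m: sorted((r.id, r.view) for r in m.records)
        assert key(t1) == key(t2) and key(e1) == key(e2)
        assert sorted(key(t1) + key(e1)) == key(man)

    def test_too_few_records(self):
        with pytest.raises(ValueError):
            split_dataset(DatasetManifest([ManifestRecord("a", "top", "a.png")]))


class TestImageSample:
    def test_view_and_shape_validation(self):
        img = np.zeros((4, 5, 3), dtype=np.uint8)
        with pytest.raises(ValueError):
            ImageSample(image=img, view="side")
        with pytest.raises(ValueError):
            ImageSample(image=img, view="top", mask=np.zeros((5, 5), dtype=np.uint8))

    def test_duplicate_ids_rejected(self):
        rec = ManifestRecord("a", "top", "a.png")
        with pytest.raises(ValueError):
            DatasetManifest([rec, rec])
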