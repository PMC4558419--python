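"""Segmentation rules: color thresholds, labelling, nucleus/compartment assignment."""

import numpy as np
import pytest

from agnorfract import (
    RgbImage,
    SegmentationConfig,
    SyntheticSpec,
    assign_compartment,
    count_per_nucleus,
    generate_image,
    label_objects,
    segment_agnor,
)
from agnorfract.segmentation import BinaryMask


def _rgb(arr):
    return RgbImage(pixels=np.asarray(arr, dtype=np.uint8), pixel_size=0.17, image_id="t")


class TestSegmentAgnor:
    def test_recovers_all_rendered_dots_noise_free(self, default_fixture):
        img, gt = default_fixture
        mask = segment_agnor(img)
        objects = label_objects(mask)
        assert len(objects) == len(gt.object_table) == 30

    def test_all_white_image_gives_empty_mask(self):
        img = _rgb(np.full((64, 64, 3), 255))
        assert not segment_agnor(img).pixels.any()

    def test_dark_green_chromogen_is_excluded_despite_low_intensity(self):
        # dark green band color passes the darkness threshold but not the green rule
        px = np.full((64, 64, 3), 255, dtype=np.uint8)
        px[10:30, 10:30] = (50, 95, 45)  # basal chromogen
        px[40:50, 40:50] = (30, 28, 26)  # silver dot
        mask = segment_agnor(_rgb(px)).pixels
        assert not mask[10:30, 10:30].any()
        assert mask[40:50, 40:50].all()

    def test_benign_image_has_no_false_positives_in_band(self):
        spec = SyntheticSpec(seed=19, noise_sd=0.0, stromal_dots_mean=0.0)
        img, gt = generate_image(spec)
        mask = segment_agnor(img).pixels
        assert not (mask & ~gt.dot_mask).any()  # nothing outside true dots, band included

    def test_non_rgb_input_failure_names_shape(self):
        grey = RgbImage.__new__(RgbImage)
        grey.pixels = np.zeros((32, 32), dtype=np.uint8)
        grey.pixel_size = 0.17
        grey.kind = "single"
        grey.image_id = "grey"
        with pytest.raises(ValueError, match=r"\(32, 32\)"):
            segment_agnor(grey)

    def test_idempotent_on_binarized_rendering(self, default_fixture):
        img, gt = default_fixture
        mask = segment_agnor(img)
        render = np.where(mask.pixels[..., None], 0, 255).astype(np.uint8).repeat(3, axis=2)
        again = segment_agnor(_rgb(render))
        assert np.array_equal(again.pixels, mask.pixels)

    def test_deterministic(self, noisy_fixture):
        img, _ = noisy_fixture
        assert np.array_equal(segment_agnor(img).pixels, segment_agnor(img).pixels)

    @pytest.mark.parametrize("sizes", [(1, 20, 60, 200)])
    def test_size_filter_is_monotone(self, noisy_fixture, sizes):
        img, _ = noisy_fixture
        counts = [
            len(label_objects(segment_agnor(img, SegmentationConfig(min_object_px=s))))
            for s in sizes
        ]
        assert counts == sorted(counts, reverse=True)


class TestLabelObjects:
    def test_diagonal_pixels_are_one_object(self):
        m = np.zeros((8, 8), dtype=bool)
        m[2, 2] = m[3, 3] = True
        objs = label_objects(BinaryMask(m, "agnor", "t"), SegmentationConfig(min_object_px=1))
        assert len(objs) == 1
        assert objs[0].pixel_area == 2

    def test_empty_mask_gives_empty_list(self):
        assert label_objects(BinaryMask(np.zeros((8, 8), bool), "agnor", "t")) == []

    def test_wrong_provenance_rejected(self):
        with pytest.raises(ValueError, match="skeleton"):
            label_objects(BinaryMask(np.zeros((8, 8), bool), "skeleton", "t"))

    def test_labels_are_row_major_by_first_pixel(self):
        m = np.zeros((16, 16), dtype=bool)
        m[1, 10] = True  # first in raster order
        m[5, 2] = True
        objs = label_objects(BinaryMask(m, "agnor", "t"), SegmentationConfig(min_object_px=1))
        assert objs[0].centroid == (1.0, 10.0)
        assert objs[1].centroid == (5.0, 2.0)


class TestCountPerNucleus:
    def test_hand_built_counts_and_mean(self):
        nuclei = np.zeros((30, 30), dtype=np.int32)
        nuclei[0:10] = 1
        nuclei[10:20] = 2
        nuclei[20:30] = 3
        m = np.zeros((30, 30), dtype=bool)
        # 2 dots in nucleus 1, 3 in 2, 4 in 3
        for i, n in enumerate((2, 3, 4)):
            for j in range(n):
                m[i * 10 + 4, 3 * j + 2] = True
        objs = label_objects(BinaryMask(m, "agnor", "t"), SegmentationConfig(min_object_px=1))
        counts, mean = count_per_nucleus(objs, nuclei)
        assert counts == {1: 2, 2: 3, 3: 4}
        assert mean == pytest.approx(3.0)

    def test_background_centroid_is_unassigned(self):
        nuclei = np.zeros((20, 20), dtype=np.int32)
        nuclei[:10] = 1
        m = np.zeros((20, 20), dtype=bool)
        m[15, 15] = True
        objs = label_objects(BinaryMask(m, "agnor", "t"), SegmentationConfig(min_object_px=1))
        counts, mean = count_per_nucleus(objs, nuclei)
        assert objs[0].nucleus_id == 0
        assert counts == {1: 0}
        assert mean == pytest.approx(0.0)

    def test_synthetic_counts_match_ground_truth(self, default_fixture):
        img, gt = default_fixture
        objs = label_objects(segment_agnor(img))
        counts, mean = count_per_nucleus(objs, gt.nucleus_mask)
        truth = gt.object_table[gt.object_table.nucleus_id > 0].groupby("nucleus_id").size()
        for nid, n in truth.items():
            assert counts[nid] == n
        assert mean == pytest.approx(truth.reindex(counts.keys(), fill_value=0).mean())


class TestAssignCompartment:
    def test_missing_map_is_an_error(self):
        with pytest.raises(ValueError, match="compartment map"):
            assign_compartment([], None)

    def test_empty_object_list_passes_through(self):
        assert assign_compartment([], np.zeros((4, 4), bool)) == []

    def test_matches_ground_truth_tags(self):
        spec = SyntheticSpec(seed=23, noise_sd=0.0, stromal_dots_mean=3.0)
        img, gt = generate_image(spec)
        objs = label_objects(segment_agnor(img))
        objs = assign_compartment(objs, gt.epithelium_mask)
        truth = gt.object_table
        assert set(truth["compartment"]) == {"epithelium", "stroma"}  # both present
        for obj in objs:
            d = np.hypot(truth["row"] - obj.centroid[0], truth["col"] - obj.centroid[1])
            assert obj.compartment == truth.iloc[int(np.argmin(d))]["compartment"]
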