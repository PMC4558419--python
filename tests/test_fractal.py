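"""Box counting, silhouette FD, skeletonization + pruning."""

import numpy as np
import pytest

from agnorfract import (
    SyntheticSpec,
    box_count_fd,
    generate_image,
    make_reference_shape,
    object_boundary_fd,
    skeleton_fd,
    skeletonize_prune,
)
from agnorfract.fractal import FD_DEGENERATE, default_box_sizes
from conftest import flood_fill_components


def grid_overlay_counts(mask, size):
    """Exhaustive oracle: occupied boxes of a size-aligned grid at offset 0."""
    h, w = mask.shape
    count = 0
    for r0 in range(0, h, size):
        for c0 in range(0, w, size):
            if mask[r0 : r0 + size, c0 : c0 + size].any():
                count += 1
    return count


class TestBoxCountFd:
    def test_counts_match_exhaustive_grid_overlay(self):
        mask = make_reference_shape("sierpinski", order=5, side=256)
        sizes = [8, 16, 32, 64]
        res = box_count_fd(mask, sizes=sizes, offsets_per_size=1)
        expected = [grid_overlay_counts(mask, s) for s in sorted(sizes, reverse=True)]
        assert res.counts.tolist() == expected

    def test_counts_nondecreasing_as_boxes_shrink(self):
        mask = make_reference_shape("rugged_blob", radius=60, amplitude=0.3, harmonics=12)
        res = box_count_fd(mask)
        assert all(a <= b for a, b in zip(res.counts, res.counts[1:]))

    def test_empty_mask_is_an_error(self):
        with pytest.raises(ValueError, match="empty"):
            box_count_fd(np.zeros((64, 64), dtype=bool))

    def test_too_few_sizes_is_an_error(self):
        with pytest.raises(ValueError, match="3 box sizes"):
            box_count_fd(np.ones((64, 64), dtype=bool), sizes=[2, 4])

    def test_translation_invariance(self):
        blob = make_reference_shape("rugged_blob", radius=120, amplitude=0.2, harmonics=10, side=512)
        shifted = np.roll(np.roll(blob, 7, axis=0), 13, axis=1)
        f0 = box_count_fd(blob).fd
        f1 = box_count_fd(shifted).fd
        assert abs(f0 - f1) < 0.02

    def test_estimates_bounded_for_planar_masks(self):
        masks = [
            make_reference_shape("line", length=256),
            make_reference_shape("disk", radius=40),
            make_reference_shape("sierpinski", order=6, side=256),
            make_reference_shape("rugged_blob", radius=50, amplitude=0.4, harmonics=20),
            np.eye(128, dtype=bool),
        ]
        for m in masks:
            fd = box_count_fd(m).fd
            assert -0.05 <= fd <= 2.05

    def test_r_squared_high_on_clean_scaling(self):
        res = box_count_fd(make_reference_shape("line", length=512))
        assert res.r_squared > 0.999
        assert res.n_scales >= 3


class TestObjectBoundaryFd:
    def test_smooth_disk_near_one(self):
        assert object_boundary_fd(make_reference_shape("disk", radius=50)) == pytest.approx(1.0, abs=0.05)

    def test_monotone_in_ruggedness_amplitude(self):
        rng = np.random.default_rng(0)
        mean_fd = []
        for amp in (0.05, 0.15, 0.30):
            fds = []
            for _ in range(50):
                blob = make_reference_shape(
                    "rugged_blob",
                    radius=30,
                    amplitude=amp,
                    harmonics=int(rng.integers(8, 16)),
                    phase=rng.uniform(0, 2 * np.pi),
                    side=96,
                )
                fds.append(object_boundary_fd(blob))
            mean_fd.append(np.mean(fds))
        assert mean_fd[0] < mean_fd[1] < mean_fd[2]

    def test_pairwise_amplitude_ordering_single_blob(self):
        lo = make_reference_shape("rugged_blob", radius=100, amplitude=0.05, harmonics=16)
        hi = make_reference_shape("rugged_blob", radius=100, amplitude=0.30, harmonics=16)
        assert object_boundary_fd(hi) > object_boundary_fd(lo)

    def test_tiny_object_gets_degenerate_flag(self):
        m = np.zeros((8, 8), dtype=bool)
        m[3, 3:5] = True
        assert object_boundary_fd(m) == FD_DEGENERATE


class TestSkeletonizePrune:
    def test_disk_reduces_to_central_few_pixels(self):
        sk = skeletonize_prune(make_reference_shape("disk", radius=30), prune_length_px=8)
        assert 1 <= int(sk.mask.sum()) <= 5
        assert sk.component_count == 1

    def test_annulus_becomes_one_closed_loop(self):
        ann = make_reference_shape("disk", radius=40) & ~make_reference_shape("disk", radius=30, side=96)
        sk = skeletonize_prune(ann, prune_length_px=5)
        assert sk.component_count == 1
        # Euler-characteristic oracle for a simple cycle: V == E
        pts = set(zip(*np.nonzero(sk.mask)))
        edges = 0
        for r, c in pts:
            for dr in (-1, 0, 1):
                for dc in (-1, 0, 1):
                    if (dr, dc) != (0, 0) and (r + dr, c + dc) in pts:
                        edges += 1
        assert edges // 2 == len(pts)

    def test_empty_mask_gives_empty_skeleton(self):
        sk = skeletonize_prune(np.zeros((32, 32), dtype=bool))
        assert not sk.mask.any()
        assert sk.component_count == 0

    def test_component_count_preserved_on_synthetic_dots(self):
        _, gt = generate_image(SyntheticSpec(seed=31, noise_sd=0.0))
        sk = skeletonize_prune(gt.dot_mask, prune_length_px=5)
        assert sk.component_count == flood_fill_components(gt.dot_mask)

    def test_skeleton_never_larger_than_source(self, default_fixture):
        _, gt = default_fixture
        sk = skeletonize_prune(gt.dot_mask)
        assert int(sk.mask.sum()) <= int(gt.dot_mask.sum())


def _dots_on_line(n=24, side=512, radius=4):
    mask = np.zeros((side, side), dtype=bool)
    disk = make_reference_shape("disk", radius=radius, side=2 * radius + 3)
    step = side // n
    for i in range(n):
        r0 = side // 2 - disk.shape[0] // 2
        c0 = min(max(i * step + step // 2 - disk.shape[1] // 2, 0), side - disk.shape[1])
        mask[r0 : r0 + disk.shape[0], c0 : c0 + disk.shape[1]] |= disk
    return mask


def _dots_scattered(n=24, side=512, radius=4, seed=0):
    rng = np.random.default_rng(seed)
    mask = np.zeros((side, side), dtype=bool)
    disk = make_reference_shape("disk", radius=radius, side=2 * radius + 3)
    k = disk.shape[0]
    placed = 0
    while placed < n:
        r0 = int(rng.integers(0, side - k))
        c0 = int(rng.integers(0, side - k))
        mask[r0 : r0 + k, c0 : c0 + k] |= disk
        placed += 1
    return mask


class TestSkeletonFd:
    def test_collinear_dots_read_like_a_line_at_coarse_scales(self):
        coarse = [16, 32, 64, 128]
        fd_dots = skeleton_fd(_dots_on_line(), sizes=coarse)
        fd_line = box_count_fd(make_reference_shape("line", length=512), sizes=coarse).fd
        assert abs(fd_dots - fd_line) < 0.2

    def test_dense_scatter_fills_more_space_than_a_line(self):
        # high density: same dot count, scattered vs collinear
        coarse = [16, 32, 64, 128]
        fd_line = skeleton_fd(_dots_on_line(n=200, radius=3), sizes=coarse)
        fd_scatter = skeleton_fd(_dots_scattered(n=200, radius=3), sizes=coarse)
        assert fd_scatter > fd_line

    def test_single_dot_is_degenerate(self):
        m = np.zeros((512, 512), dtype=bool)
        m[250:254, 250:254] = True
        assert skeleton_fd(m) == FD_DEGENERATE

    def test_empty_mask_is_an_error(self):
        with pytest.raises(ValueError, match="empty"):
            skeleton_fd(np.zeros((128, 128), dtype=bool))


def test_default_box_sizes_span_powers_of_two():
    assert default_box_sizes((512, 512)) == [128, 64, 32, 16, 8, 4, 2]
    assert default_box_sizes((64, 80)) == [16, 8, 4, 2]
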