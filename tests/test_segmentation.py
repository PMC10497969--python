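"""Classical segmentation chain: resampling, preprocessing, thresholding,
artifact filters, watershed splitting and moment-based ellipsoid fitting."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from chondrosim import segmentation as seg
from chondrosim.synthetic import NoiseModel, render_stack
from chondrosim.types import EllipsoidCell, EllipsoidSet, ImageStack, LabeledVolume


def binary_volume(mask_array, voxel=1.0):
    return LabeledVolume(mask_array.astype(np.int32), np.full(3, voxel))


class TestResample:
    def test_isotropic_passthrough(self):
        stack = ImageStack(np.random.default_rng(0).integers(0, 100, (8, 8, 8)).astype(np.uint16),
                           np.full(3, 0.5))
        out = seg.resample_isotropic(stack)
        assert out is stack

    def test_shape_arithmetic(self):
        cell = EllipsoidCell([8, 20, 20], [6, 6, 6], np.eye(3), 1)
        stack, _ = render_stack(EllipsoidSet([cell], (16, 40, 40)), (1.0, 0.1099, 0.1099))
        out = seg.resample_isotropic(stack)
        assert out.shape[0] == round(16 * 1.0 / 0.1099)
        assert np.allclose(out.voxel_size, 0.1099)
        # physical extent preserved within one voxel per axis
        assert np.all(np.abs(out.extent - stack.extent) <= out.voxel_size + 1e-9)

    def test_intensity_preserved(self):
        cell = EllipsoidCell([8, 20, 20], [6, 6, 6], np.eye(3), 1)
        stack, _ = render_stack(EllipsoidSet([cell], (16, 40, 40)), (1.0, 0.1099, 0.1099))
        out = seg.resample_isotropic(stack)
        t_in = stack.data.astype(float).sum() * np.prod(stack.voxel_size)
        t_out = out.data.astype(float).sum() * np.prod(out.voxel_size)
        assert abs(t_out - t_in) / t_in < 0.01

    def test_single_slice_rejected(self):
        stack = ImageStack(np.zeros((1, 8, 8), dtype=np.uint16), (1, 0.1, 0.1))
        with pytest.raises(ValueError):
            seg.resample_isotropic(stack)


class TestPreprocess:
    def test_constant_image_flattens_to_constant(self):
        stack = ImageStack(np.full((10, 10, 10), 500, dtype=np.uint16), np.ones(3))
        out = seg.preprocess(stack, seg.SegmentationConfig(stretch_contrast=False))
        assert np.allclose(out.data, out.data.flat[0], atol=1e-6)

    def test_illumination_gradient_flattened(self):
        """Slice-mean variation reduced at least 5x by background removal."""
        pop = EllipsoidSet(
            [EllipsoidCell([20, 20, 20], [7, 7, 7], np.eye(3), 1)], np.full(3, 40.0)
        )
        noise = NoiseModel(illumination_gradient=(0.4, 0, 0), seed=0)
        stack, gt = render_stack(pop, (1, 1, 1), noise)
        out = seg.preprocess(stack, seg.SegmentationConfig(stretch_contrast=False))
        bg = gt.labels == 0

        def slice_mean_std(data):
            means = [data[z][bg[z]].mean() for z in range(data.shape[0])]
            return np.std(means)

        assert slice_mean_std(out.data) < slice_mean_std(stack.data.astype(float)) / 5

    def test_clean_cell_shape_preserved(self):
        """After the full chain, foreground matches ground truth closely."""
        pop = EllipsoidSet(
            [EllipsoidCell([20, 20, 20], [8, 7, 6], np.eye(3), 1)], np.full(3, 40.0)
        )
        stack, gt = render_stack(pop, (0.5, 0.5, 0.5), NoiseModel())
        pre = seg.preprocess(stack)
        mask = seg.auto_threshold(pre).labels > 0
        gt_mask = gt.labels > 0
        jaccard = (mask & gt_mask).sum() / (mask | gt_mask).sum()
        assert jaccard >= 0.95


class TestAutoThreshold:
    def test_bimodal_exact(self):
        data = np.full((6, 6, 6), 10, dtype=np.uint16)
        data[2:4, 2:4, 2:4] = 200
        mask = seg.auto_threshold(ImageStack(data, np.ones(3)))
        np.testing.assert_array_equal(mask.labels.astype(bool), data == 200)

    def test_inverted_polarity_complementary(self):
        data = np.full((6, 6, 6), 10, dtype=np.uint16)
        data[2:4, 2:4, 2:4] = 200
        stack = ImageStack(data, np.ones(3))
        normal = seg.auto_threshold(stack).labels.astype(bool)
        flipped = seg.auto_threshold(stack, invert=True).labels.astype(bool)
        np.testing.assert_array_equal(normal, ~flipped)

    def test_constant_image_raises(self):
        stack = ImageStack(np.full((5, 5, 5), 7, dtype=np.uint16), np.ones(3))
        with pytest.raises(ValueError, match="no threshold"):
            seg.auto_threshold(stack)

    def test_clean_stack_jaccard(self, clean_population_stack):
        _, stack, gt = clean_population_stack
        mask = seg.auto_threshold(seg.preprocess(stack)).labels > 0
        gt_mask = gt.labels > 0
        assert (mask & gt_mask).sum() / (mask | gt_mask).sum() >= 0.9


class TestFilterArtifacts:
    def test_small_volume_removed(self):
        # 150 µm³ blob at 1 µm voxels: below the 200 µm³ volume gate
        mask = np.zeros((20, 20, 20), bool)
        mask[5:11, 5:10, 5:10] = True  # 6*5*5 = 150 voxels, slices 25 µm²
        out = seg.filter_artifacts(binary_volume(mask))
        assert out.labels.sum() == 0

    def test_giant_slice_component_removed(self):
        # one slice with a 400 µm² component: above the 300 µm² slice gate
        mask = np.zeros((10, 30, 30), bool)
        mask[4, 5:25, 5:25] = True  # 400 voxels in-slice
        out = seg.filter_artifacts(binary_volume(mask))
        assert out.labels[4].sum() == 0

    def test_valid_cell_retained(self):
        # 256 µm³ with largest slice 64 µm²: passes both gates
        mask = np.zeros((20, 20, 20), bool)
        mask[4:8, 6:14, 6:14] = True  # 4 slices of 64 µm² each
        out = seg.filter_artifacts(binary_volume(mask))
        assert out.labels.sum() == mask.sum()

    def test_idempotent(self, clean_population_stack):
        _, stack, _ = clean_population_stack
        mask = seg.auto_threshold(seg.preprocess(stack))
        once = seg.filter_artifacts(mask)
        twice = seg.filter_artifacts(once)
        np.testing.assert_array_equal(once.labels, twice.labels)


class TestSplitCells:
    def test_overlapping_spheres_split(self):
        c1 = EllipsoidCell([20, 20, 14], [8, 8, 8], np.eye(3), 1)
        c2 = EllipsoidCell([20, 20, 26], [8, 8, 8], np.eye(3), 2)
        _, gt = render_stack(EllipsoidSet([c1, c2], (40, 40, 40)), (0.5, 0.5, 0.5))
        mask = binary_volume(gt.labels > 0, 0.5)
        out = seg.split_cells(mask)
        assert len(out.instance_labels) == 2
        from scipy import ndimage

        for lab in out.instance_labels:
            com = np.array(ndimage.center_of_mass(out.labels == lab)) * 0.5
            d = min(np.linalg.norm(com - c1.center), np.linalg.norm(com - c2.center))
            assert d < 2.0

    def test_single_blob_single_label(self):
        c = EllipsoidCell([15, 15, 15], [9, 7, 6], np.eye(3), 1)
        _, gt = render_stack(EllipsoidSet([c], (30, 30, 30)), (0.5, 0.5, 0.5))
        out = seg.split_cells(binary_volume(gt.labels > 0, 0.5))
        assert len(out.instance_labels) == 1

    def test_empty_mask(self):
        out = seg.split_cells(binary_volume(np.zeros((5, 5, 5), bool)))
        assert len(out.instance_labels) == 0

    def test_labels_inside_filled_mask(self, clean_population_stack):
        _, stack, _ = clean_population_stack
        from scipy import ndimage

        mask = seg.filter_artifacts(seg.auto_threshold(seg.preprocess(stack)))
        out = seg.split_cells(mask)
        filled = ndimage.binary_fill_holes(mask.labels > 0)
        assert not np.any((out.labels > 0) & ~filled)


class TestFitEllipsoids:
    def _render_single(self, semi, rotation=np.eye(3), voxel=0.5):
        pad = max(semi) + 3
        box = np.full(3, 2 * pad)
        cell = EllipsoidCell(box / 2, semi, rotation, 1)
        _, gt = render_stack(EllipsoidSet([cell], box), np.full(3, voxel))
        return cell, gt

    def test_axis_aligned_recovery(self):
        cell, gt = self._render_single(np.array([10.0, 8.0, 6.0]))
        fit = seg.fit_ellipsoids(gt).cells[0]
        assert np.all(np.abs(fit.semi_axes - cell.semi_axes) / cell.semi_axes < 0.05)
        assert abs(fit.volume - gt.volume_of(1)) / gt.volume_of(1) < 0.02
        assert np.linalg.norm(fit.center - cell.center) < 0.5

    def test_sphere_symmetry(self):
        _, gt = self._render_single(np.array([8.0, 8.0, 8.0]))
        fit = seg.fit_ellipsoids(gt).cells[0]
        assert (fit.semi_axes.max() - fit.semi_axes.min()) / fit.semi_axes.mean() < 0.03

    def test_rotated_principal_axis(self):
        rot = Rotation.from_euler("zyx", [30, 20, 10], degrees=True).as_matrix()
        cell, gt = self._render_single(np.array([12.0, 7.0, 5.0]), rot)
        fit = seg.fit_ellipsoids(gt).cells[0]
        cos = abs(np.dot(fit.rotation[:, 0], cell.rotation[:, 0]))
        assert np.degrees(np.arccos(min(cos, 1.0))) < 5.0

    def test_volume_identity(self, clean_population_stack):
        """Sum of fitted volumes equals the labeled voxel volume exactly."""
        _, _, gt = clean_population_stack
        fits = seg.fit_ellipsoids(gt)
        total_fit = sum(c.volume for c in fits)
        total_vox = np.count_nonzero(gt.labels) * gt.voxel_volume
        assert total_fit == pytest.approx(total_vox, rel=1e-9)

    def test_tiny_label_skipped(self):
        lab = np.zeros((5, 5, 5), dtype=np.int32)
        lab[2, 2, 2] = 1
        lab[0:3, 0:3, 0] = 2
        with pytest.warns(UserWarning):
            fits = seg.fit_ellipsoids(LabeledVolume(lab, np.ones(3)))
        assert [c.label for c in fits] == [2]


def test_end_to_end_recovery(clean_population_stack):
    """Detected count equals generated count; fitted volumes within 10%."""
    pop, stack, _ = clean_population_stack
    labels, fitted = seg.segment_stack(stack)
    assert len(fitted) == len(pop)
    for fit in fitted:
        gt_cell = min(pop.cells, key=lambda c: np.linalg.norm(c.center - fit.center))
        assert abs(fit.volume - gt_cell.volume) / gt_cell.volume < 0.10
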