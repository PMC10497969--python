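"""Geometry assembly: intersection graph, void repair, surface meshes,
smoothing, decimation and voxelization."""

import numpy as np
import pytest
import trimesh

from chondrosim import geometry as g
from chondrosim.synthetic import render_stack
from chondrosim.types import EllipsoidCell, EllipsoidSet

from conftest import make_sphere_geometry


def unit_sphere(center, label=1, r=1.0):
    return EllipsoidCell(center, np.full(3, r), np.eye(3), label)


class TestIntersectionGraph:
    def test_pair_count_formula(self):
        pop = EllipsoidSet(
            [unit_sphere([5.0 * k, 0, 0], k + 1) for k in range(30)], None
        )
        ig = g.build_intersection_graph(pop)
        assert ig.n_checks == 30 * 29 // 2

    def test_single_cell(self):
        ig = g.build_intersection_graph(EllipsoidSet([unit_sphere([0, 0, 0])]))
        assert ig.n_checks == 0 and ig.edges == []

    @pytest.mark.parametrize("d,expect", [(1.5, True), (3.0, False)])
    def test_unit_sphere_pair(self, d, expect):
        pop = EllipsoidSet([unit_sphere([0, 0, 0], 1), unit_sphere([0, 0, d], 2)])
        ig = g.build_intersection_graph(pop)
        assert ((1, 2) in ig.edges) is expect

    def test_grazing_touch_detected(self):
        pop = EllipsoidSet([unit_sphere([0, 0, 0], 1), unit_sphere([0, 0, 2.0], 2)])
        assert (1, 2) in g.build_intersection_graph(pop).edges


class TestVoidRepair:
    def ring(self):
        cells = [
            EllipsoidCell(
                [0, 5.5 * np.sin(2 * np.pi * k / 3), 5.5 * np.cos(2 * np.pi * k / 3)],
                [5, 5, 5],
                np.eye(3),
                k + 1,
            )
            for k in range(3)
        ]
        return EllipsoidSet(cells)

    def test_ring_yields_single_filler(self):
        cells = self.ring()
        ig = g.build_intersection_graph(cells)
        assert set(ig.edges) == {(1, 2), (1, 3), (2, 3)}
        fillers = g.detect_and_fill_voids(ig, cells)
        assert len(fillers) == 1
        f = fillers[0]
        # the pocket center is on the ring axis, near the origin
        assert np.linalg.norm(f.center) < 1.0
        assert f.radius > 0

    def test_filler_leaves_no_enclosed_cavity(self):
        """Flood fill from the domain boundary reaches every non-cell voxel."""
        from scipy import ndimage

        cells = self.ring()
        fillers = g.detect_and_fill_voids(g.build_intersection_graph(cells), cells)
        res = 0.25
        lo, hi = np.full(3, -13.0), np.full(3, 13.0)
        shape = np.ceil((hi - lo) / res).astype(int)
        grids = np.meshgrid(
            *[lo[a] + (np.arange(shape[a]) + 0.5) * res for a in range(3)], indexing="ij"
        )
        pts = np.stack(grids, axis=-1)
        solid = np.zeros(shape, bool)
        for c in cells:
            solid |= c.contains(pts)
        for f in fillers:
            solid |= np.sum((pts - f.center) ** 2, axis=-1) <= f.radius**2
        bg_labels, _ = ndimage.label(~solid)
        border = np.zeros(shape, bool)
        for ax in range(3):
            sl = [slice(None)] * 3
            sl[ax] = 0
            border[tuple(sl)] = True
            sl[ax] = -1
            border[tuple(sl)] = True
        outside = np.unique(bg_labels[border & ~solid])
        enclosed = (~solid) & ~np.isin(bg_labels, outside)
        assert enclosed.sum() == 0

    def test_chain_no_filler(self):
        cells = EllipsoidSet([unit_sphere([0, 0, 0], 1, 5), unit_sphere([0, 0, 8], 2, 5)])
        assert g.detect_and_fill_voids(g.build_intersection_graph(cells), cells) == []

    def test_disjoint_no_filler(self):
        cells = EllipsoidSet([unit_sphere([0, 0, 0], 1), unit_sphere([0, 0, 10], 2)])
        assert g.detect_and_fill_voids(g.build_intersection_graph(cells), cells) == []


class TestSurfaceMesh:
    def test_voxelized_sphere_fidelity(self):
        c = EllipsoidCell([15, 15, 15], [10, 10, 10], np.eye(3), 1)
        _, lab = render_stack(EllipsoidSet([c], np.full(3, 30.0)), (0.5, 0.5, 0.5))
        mesh = g.extract_surface_mesh(lab)[1]
        assert mesh.is_watertight
        assert abs(mesh.volume - c.volume) / c.volume < 0.02
        assert abs(mesh.area - 4 * np.pi * 100) / (4 * np.pi * 100) < 0.05

    def test_single_voxel(self):
        lab = np.zeros((5, 5, 5), dtype=np.int32)
        lab[2, 2, 2] = 1
        from chondrosim.types import LabeledVolume

        mesh = g.extract_surface_mesh(LabeledVolume(lab, np.ones(3)))[1]
        assert mesh.is_watertight and 0 < mesh.volume <= 1.0

    def test_two_labels_two_components(self):
        lab = np.zeros((10, 10, 10), dtype=np.int32)
        lab[1:4, 1:4, 1:4] = 1
        lab[6:9, 6:9, 6:9] = 2
        from chondrosim.types import LabeledVolume

        meshes = g.extract_surface_mesh(LabeledVolume(lab, np.ones(3)))
        assert set(meshes) == {1, 2}
        assert all(m.is_watertight for m in meshes.values())

    def test_border_touching_label_closes(self):
        lab = np.zeros((6, 6, 6), dtype=np.int32)
        lab[0:3, 0:3, 0:3] = 1  # touches the volume border
        from chondrosim.types import LabeledVolume

        mesh = g.extract_surface_mesh(LabeledVolume(lab, np.ones(3)))[1]
        assert mesh.is_watertight and mesh.volume > 0

    def test_level_set_fidelity_fine(self):
        """Smooth-field marching cubes of an ellipsoid: errors under 1%."""
        semi = np.array([10.0, 8.0, 6.0])
        vox = 0.25
        box = 2 * (semi + 2.0)
        cell = EllipsoidCell(box / 2, semi, np.eye(3), 1)
        shape = np.ceil(box / vox).astype(int)
        grids = np.meshgrid(*[(np.arange(s) + 0.5) * vox for s in shape], indexing="ij")
        q = np.sum(((np.stack(grids, -1) - cell.center) / semi) ** 2, axis=-1)
        mesh = g.extract_isosurface(q, 1.0, np.full(3, vox))
        dv, da = g.mesh_fidelity_report(
            mesh, cell.volume, g.ellipsoid_surface_area(semi)
        )
        assert abs(dv) < 1.0 and abs(da) < 1.0


class TestTaubin:
    @pytest.fixture(scope="class")
    def sphere_mesh(self):
        c = EllipsoidCell([15, 15, 15], [10, 10, 10], np.eye(3), 1)
        _, lab = render_stack(EllipsoidSet([c], np.full(3, 30.0)), (0.5, 0.5, 0.5))
        return g.extract_surface_mesh(lab)[1]

    def test_zero_iterations_identity(self, sphere_mesh):
        out = g.taubin_smooth(sphere_mesh, iterations=0)
        np.testing.assert_array_equal(out.vertices, sphere_mesh.vertices)

    def test_zero_lambda_identity(self, sphere_mesh):
        out = g.taubin_smooth(sphere_mesh, lamb=0.0, iterations=10)
        np.testing.assert_array_equal(out.vertices, sphere_mesh.vertices)

    def test_volume_preserved_vs_laplacian(self, sphere_mesh):
        v0 = sphere_mesh.volume
        taubin = g.taubin_smooth(sphere_mesh, 0.5, -0.53, 10)
        laplace = g.taubin_smooth(sphere_mesh, 0.5, 0.0, 10)
        assert abs(taubin.volume - v0) < abs(laplace.volume - v0)

    def test_connectivity_unchanged(self, sphere_mesh):
        out = g.taubin_smooth(sphere_mesh, 0.5, -0.53, 5)
        np.testing.assert_array_equal(out.faces, sphere_mesh.faces)
        assert out.is_watertight


class TestDecimate:
    def test_identity_at_current_count(self):
        m = trimesh.creation.icosphere(3)
        out = g.decimate(m, len(m.faces))
        assert len(out.faces) == len(m.faces)

    def test_sphere_reduction_envelope(self):
        """Large reduction keeps volume within 5% and area within 15%."""
        m = trimesh.creation.icosphere(4, radius=10.0)  # 5120 faces
        out = g.decimate(m, 512)
        assert len(out.faces) <= 512
        assert out.is_watertight
        assert abs(out.volume - m.volume) / m.volume < 0.05
        assert abs(out.area - m.area) / m.area < 0.15

    def test_aggressive_target_stays_manifold(self):
        import warnings

        m = trimesh.creation.icosphere(1)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # may stop early, legitimately
            out = g.decimate(m, 4)
        assert out.is_watertight and len(out.faces) >= 4


class TestFidelityReport:
    def test_identity(self):
        m = trimesh.creation.icosphere(3, radius=5.0)
        dv, da = g.mesh_fidelity_report(m, m.volume, m.area)
        assert dv == 0.0 and da == 0.0

    def test_scaling_law(self):
        m = trimesh.creation.icosphere(3, radius=5.0)
        s = m.copy()
        s.apply_scale(1.01)
        dv, da = g.mesh_fidelity_report(s, m.volume, m.area)
        assert dv == pytest.approx((1.01**3 - 1) * 100, rel=1e-6)
        assert da == pytest.approx((1.01**2 - 1) * 100, rel=1e-6)


class TestVoxelize:
    def test_no_cells_all_buffer(self):
        geom = g.voxelize_geometry(EllipsoidSet([], np.full(3, 20.0)), np.full(3, 20.0), 1.0)
        assert geom.volume_ratio == 0.0
        assert geom.membrane_face_count == 0

    def test_sphere_effective_membrane_area(self):
        """Normal-weighted membrane area approximates the true sphere area;
        the raw staircase area carries the documented ~3/2 bias."""
        geom = make_sphere_geometry(radius_um=8.0, box_um=40.0, n=40)
        true_area = 4 * np.pi * 64
        weighted = sum(
            (w[mask]).sum() * geom.face_area(ax)
            for ax, (w, mask) in enumerate(
                zip(geom.membrane_normal_weights(), geom.membrane_face_masks())
            )
        )
        assert abs(weighted - true_area) / true_area < 0.15
        assert geom.membrane_area > 1.3 * true_area  # staircase bias is real

    def test_fused_cells_share_no_membrane(self):
        """Two intersecting cells form one cytoplasm with no interior wall."""
        from scipy import ndimage

        box = np.full(3, 40.0)
        a = EllipsoidCell([20, 20, 15], [8, 8, 8], np.eye(3), 1)
        b = EllipsoidCell([20, 20, 25], [8, 8, 8], np.eye(3), 2)
        geom = g.voxelize_geometry(EllipsoidSet([a, b], box), box, 0.5)
        _, n_components = ndimage.label(geom.materials)
        assert n_components == 1
        separate = [
            g.voxelize_geometry(EllipsoidSet([c], box), box, 0.5) for c in (a, b)
        ]
        assert geom.membrane_face_count < sum(s.membrane_face_count for s in separate)

    def test_volume_ratio_converges(self):
        box = np.full(3, 40.0)
        cell = EllipsoidCell([20, 20, 20], [9, 7, 6], np.eye(3), 1)
        cells = EllipsoidSet([cell], box)
        analytic = cell.volume / 40.0**3
        errs = [
            abs(g.voxelize_geometry(cells, box, v).volume_ratio - analytic) / analytic
            for v in (2.0, 1.0, 0.5)
        ]
        assert errs[2] < errs[0]

    def test_clipped_cell_warns(self):
        box = np.full(3, 20.0)
        cell = EllipsoidCell([2, 10, 10], [5, 5, 5], np.eye(3), 1)
        with pytest.warns(UserWarning, match="clipped"):
            g.voxelize_geometry(EllipsoidSet([cell], box), box, 1.0)

    def test_refine_preserves_geometry(self):
        geom = make_sphere_geometry(n=16)
        fine = geom.refine(2)
        assert fine.shape == (32, 32, 32)
        assert fine.volume_ratio == geom.volume_ratio
        np.testing.assert_allclose(fine.box, geom.box)
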