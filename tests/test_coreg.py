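"""RPI painting, rigid resampling, quadrant aggregation."""

import dataclasses

import numpy as np
import pytest

from aaaquant import biomech, coreg, phantom, pipeline, segmentation
from aaaquant.errors import DataError, UnsupportedFeatureError
from aaaquant.imaging_io import ImageVolume


def tiny_volume(shape=(10, 12, 8), spacing=(1.0, 1.0, 1.0), origin=(0, 0, 0)):
    return ImageVolume(np.zeros(shape), spacing, origin)


def brute_force_nearest(vol, pos):
    """All-voxel scan oracle with the documented lowest-linear-index tie rule."""
    coords = np.stack(np.meshgrid(*[vol.axis_coords(a) for a in range(3)],
                                  indexing="ij"), axis=-1)
    d2 = ((coords - np.asarray(pos)) ** 2).sum(axis=-1)
    flat = np.round(d2, 12).ravel()
    return np.unravel_index(int(np.argmin(flat)), vol.shape)


class TestNearestVoxel:
    def test_node_at_voxel_center(self):
        vol = tiny_volume(spacing=(0.5, 1.0, 2.0), origin=(-1.0, 0.0, 3.0))
        idx = coreg.nearest_voxel_index(vol, np.array([[-1.0 + 2 * 0.5, 3.0, 7.0]]))
        assert tuple(idx[0]) == (2, 3, 2)

    def test_equidistant_tie_goes_to_lowest_linear_index(self):
        vol = tiny_volume()
        # exactly halfway between voxels (1, 2, 3) and (2, 2, 3) along x
        idx = coreg.nearest_voxel_index(vol, np.array([[1.5, 2.0, 3.0]]))
        assert tuple(idx[0]) == (1, 2, 3)
        # halfway on every axis: the corner with all-lower indices
        idx = coreg.nearest_voxel_index(vol, np.array([[1.5, 2.5, 3.5]]))
        assert tuple(idx[0]) == (1, 2, 3)

    def test_against_brute_force_scan_for_random_nodes(self, rng):
        vol = tiny_volume(shape=(9, 7, 11), spacing=(0.8, 1.3, 0.6),
                          origin=(-2.0, 1.0, 0.5))
        lo, hi = vol.index_to_world([0, 0, 0]), vol.index_to_world([8, 6, 10])
        for _ in range(100):
            pos = rng.uniform(lo, hi)
            fast = tuple(coreg.nearest_voxel_index(vol, pos[None, :])[0])
            assert fast == brute_force_nearest(vol, pos)
            # distance never exceeds half the voxel diagonal
            d = np.linalg.norm(vol.index_to_world(np.array(fast)) - pos)
            assert d <= np.linalg.norm(np.array(vol.spacing)) / 2 + 1e-9


@pytest.fixture(scope="module")
def painted_setup(small_spec):
    labels, mesh = phantom.generate_geometry(small_spec, n_theta=32, n_z=48)
    cta = phantom.simulate_cta(labels, small_spec)
    stress = biomech.wall_stress_fea(mesh)
    strength = biomech.wall_strength(small_spec.subject, n_nodes=mesh.n_nodes)
    field = biomech.compute_rpi(stress, strength)
    painted = coreg.paint_rpi(field, mesh, cta)
    return labels, mesh, cta, field, painted


class TestPainting:
    def test_intensity_strictly_above_background(self, painted_setup):
        _, _, cta, _, painted = painted_setup
        vals = painted.volume.data[painted.painted_mask]
        assert vals.min() > cta.data.max()

    def test_unpaint_recovers_node_means_exactly(self, painted_setup):
        _, mesh, cta, field, painted = painted_setup
        rec = coreg.unpaint(painted)
        idx = coreg.nearest_voxel_index(cta, mesh.nodes)
        # oracle: group node rpi values by voxel, compare means
        from collections import defaultdict
        groups = defaultdict(list)
        for node, (i, j, k) in enumerate(idx):
            groups[(i, j, k)].append(field.rpi[node])
        for (i, j, k), vals in groups.items():
            assert rec[i, j, k] == pytest.approx(np.mean(vals), rel=1e-12)

    def test_painted_voxels_near_wall_mask(self, painted_setup, small_spec):
        labels, _, _, _, painted = painted_setup
        from scipy import ndimage
        wall = labels.data == 2
        near_wall = ndimage.binary_dilation(wall, iterations=1)
        assert np.all(near_wall[painted.painted_mask])

    def test_out_of_grid_nodes_skipped_and_counted(self, small_spec):
        labels, mesh = phantom.generate_geometry(small_spec, n_theta=16, n_z=16)
        cta = phantom.simulate_cta(labels, small_spec)
        nodes = mesh.nodes.copy()
        nodes[:5, 2] = 1e4
        far = dataclasses.replace(mesh, nodes=nodes)
        field = biomech.compute_rpi(np.ones(mesh.n_nodes), np.ones(mesh.n_nodes))
        painted = coreg.paint_rpi(field, far, cta)
        assert painted.n_nodes_skipped == 5


class TestResample:
    def test_identity_same_grid_bit_identical(self, rng):
        vol = ImageVolume(rng.normal(size=(8, 9, 10)), (1, 1, 1))
        painted = coreg.PaintedRPIVolume(vol, offset=5.0, scale=2.0)
        out = coreg.resample_to_pet(painted, np.eye(4), vol)
        assert np.array_equal(out.volume.data, vol.data)

    def test_lattice_translation_round_trip(self, rng):
        vol = ImageVolume(rng.normal(size=(8, 8, 8)), (1, 1, 1))
        painted = coreg.PaintedRPIVolume(vol, offset=0.0, scale=1.0)
        T = np.eye(4)
        T[:3, 3] = [2.0, -1.0, 3.0]
        fwd = coreg.resample_to_pet(painted, T, vol)
        back = coreg.resample_to_pet(fwd, np.linalg.inv(T), vol)
        # interior voxels (those not pushed off-grid) are restored exactly
        inner = np.zeros(vol.shape, dtype=bool)
        inner[3:6, 3:6, 3:5] = True
        assert np.array_equal(back.volume.data[inner], vol.data[inner])

    def test_90deg_rotation_matches_rotating_the_mesh(self, small_spec):
        labels, mesh = phantom.generate_geometry(small_spec, n_theta=16, n_z=16)
        ref = ImageVolume(np.zeros(labels.shape), labels.spacing, labels.origin)
        field = biomech.compute_rpi(np.linspace(0, 10, mesh.n_nodes),
                                    np.full(mesh.n_nodes, 10.0))
        painted = coreg.paint_rpi(field, mesh, ref, offset=100.0, scale=10.0)
        # rotate +90 deg about the z axis through the grid center (x,y origin 0)
        c, s = 0.0, 1.0
        T = np.array([[c, -s, 0, 0], [s, c, 0, 0], [0, 0, 1, 0], [0, 0, 0, 1.0]])
        resampled = coreg.resample_to_pet(painted, T, ref)
        rot_nodes = mesh.nodes @ np.array([[c, s, 0], [-s, c, 0], [0, 0, 1.0]])
        rot_mesh = dataclasses.replace(mesh, nodes=rot_nodes)
        painted_rot = coreg.paint_rpi(field, rot_mesh, ref, offset=100.0, scale=10.0)
        a, b = resampled.volume.data, painted_rot.volume.data
        both = (a != 0) & (b != 0)
        # voxelization at the two paths may disagree on isolated boundary
        # voxels; the overwhelming majority must agree exactly
        assert both.sum() > 0.9 * max((a != 0).sum(), (b != 0).sum())
        np.testing.assert_allclose(a[both], b[both], atol=1e-9)

    def test_non_rigid_transform_rejected(self, rng):
        vol = ImageVolume(np.zeros((4, 4, 4)), (1, 1, 1))
        painted = coreg.PaintedRPIVolume(vol, 1.0, 1.0)
        T = np.eye(4)
        T[0, 0] = 2.0  # scaling is not rigid
        with pytest.raises(UnsupportedFeatureError):
            coreg.resample_to_pet(painted, T, vol)


class TestQuadrantRPI:
    def test_axisymmetric_quadrants_equal_within_2pct(self, small_spec):
        res = pipeline.analyze_subject(small_spec, slab_halfwidth_mm=1.5,
                                       erosion_radius_mm=1.5)
        means = res.quadrant_rpi["mean_rpi"].to_numpy()
        assert means.max() / means.min() - 1 < 0.02

    def test_posterior_bulge_peaks_posterior(self, small_spec):
        """A posterior bulge narrow enough to sit inside the posterior
        quadrant raises that quadrant's mean curvature radius, hence its
        membrane stress and RPI (a bump wider than the quadrant instead
        elevates the flank quadrants, where its curvature flattens the
        wall)."""
        spec = small_spec
        sig = np.radians(15.0)

        def radius(z, th):
            base = 9.0 + 2.0 * np.exp(-(z - 10.0) ** 2 / 32.0)
            # angular distance from posterior (-y, i.e. theta = 270 deg)
            phi = np.arctan2(np.sin(th - 1.5 * np.pi), np.cos(th - 1.5 * np.pi))
            return base + 1.5 * np.exp(-(z - 10.0) ** 2 / 32.0) \
                * np.exp(-0.5 * (phi / sig) ** 2)

        mesh = biomech.tube_mesh(radius, 2.0, 30.0, n_theta=72, n_z=56,
                                 thickness=1.5, clamp="both", pressure_mmHg=120)
        labels, _ = phantom.generate_geometry(spec, n_theta=16, n_z=16)
        seg = segmentation.segment(labels, spec.landmark_z_mm, 1.5, 1.5)
        cta = phantom.simulate_cta(labels, spec)
        stress = biomech.wall_stress_fea(mesh)
        strength = biomech.wall_strength(spec.subject, n_nodes=mesh.n_nodes)
        painted = coreg.paint_rpi(biomech.compute_rpi(stress, strength), mesh, cta)
        q = coreg.quadrant_rpi(painted, seg).set_index("region")
        assert q["mean_rpi"].idxmax() == "posterior"

    def test_empty_intersection_raises(self, small_segmentation, small_spec):
        vol = ImageVolume(np.zeros(small_segmentation.labels.shape),
                          small_segmentation.labels.spacing,
                          small_segmentation.labels.origin)
        painted = coreg.PaintedRPIVolume(vol, 1.0, 1.0)
        with pytest.raises(DataError, match="registration|MAS"):
            coreg.quadrant_rpi(painted, small_segmentation)
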