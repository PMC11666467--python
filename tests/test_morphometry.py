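"""Per-instance measurements: distances, volumes, surfaces, flatness, EdU."""

import numpy as np
import pytest

from villimorph import (
    BinaryMask,
    LabelVolume,
    PointSet,
    edu_migration_distance,
    geodesic_distance,
    organoid_area,
    villus_crypt_ratio,
    villus_flatness,
    villus_length,
    villus_surface,
    villus_volume,
)
from villimorph.crypts import BaseSurface
from villimorph._graph import dijkstra_reference
from conftest import random_blob_mask


class TestGeodesicDistance:
    def test_single_voxel_is_zero(self):
        inst = np.zeros((3, 3, 3), bool)
        inst[1, 1, 1] = True
        field = geodesic_distance(inst, inst, (1, 1, 1))
        assert field[1, 1, 1] == 0.0

    def test_straight_run_at_z_step(self):
        """11 voxels along z at dz = 2.15 μm span 21.5 μm."""
        inst = np.zeros((11, 1, 1), bool)
        inst[:, 0, 0] = True
        src = np.zeros_like(inst)
        src[0, 0, 0] = True
        field = geodesic_distance(inst, src, (2.15, 1, 1))
        assert field[10, 0, 0] == pytest.approx(21.5, rel=1e-12)

    def test_empty_sources_error(self):
        inst = np.ones((2, 2, 2), bool)
        with pytest.raises(ValueError, match="source"):
            geodesic_distance(inst, np.zeros_like(inst), (1, 1, 1))

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_independent_dijkstra(self, seed):
        rng = np.random.default_rng(seed)
        shape = tuple(rng.integers(8, 20, 3))
        inst = random_blob_mask(rng, shape=shape, threshold=0.45)
        if not inst.any():
            pytest.skip("degenerate draw")
        vox = np.argwhere(inst)
        src = np.zeros(shape, bool)
        src[tuple(vox[rng.integers(len(vox))])] = True
        spacing = tuple(rng.uniform(0.4, 2.5, 3).round(3))
        field = geodesic_distance(inst, src, spacing)
        ref = dijkstra_reference(inst, src, spacing)
        finite = inst & np.isfinite(ref)
        np.testing.assert_allclose(field[finite], ref[finite], rtol=1e-9)


class TestVillusLength:
    def _cylinder(self, height_vox, dz):
        labels = np.zeros((height_vox + 2, 7, 7), np.int32)
        labels[1:, 2:5, 2:5] = 1
        base = np.zeros_like(labels, bool)
        base[1] = labels[1] > 0
        return LabelVolume(labels, (dz, 1, 1)), BaseSurface(base, (dz, 1, 1))

    def test_upright_cylinder(self):
        labels, base = self._cylinder(50, 1.0)
        rows = villus_length(labels, base)
        diag = np.sqrt(3.0)
        assert rows[0]["length"] == pytest.approx(50.0, abs=diag)

    def test_spacing_doubling_doubles_length(self):
        labels1, base1 = self._cylinder(30, 1.0)
        rows1 = villus_length(labels1, base1)
        labels2 = LabelVolume(labels1.data, (2.0, 2.0, 2.0))
        base2 = BaseSurface(base1.voxels, (2.0, 2.0, 2.0))
        rows2 = villus_length(labels2, base2)
        assert rows2[0]["length"] == pytest.approx(2 * rows1[0]["length"], rel=1e-12)

    def test_l_shaped_tube_matches_dijkstra(self):
        labels = np.zeros((54, 54, 5), np.int32)
        labels[1:52, 1:4, 1:4] = 1
        labels[49:52, 1:52, 1:4] = 1
        base = np.zeros_like(labels, bool)
        base[1] = labels[1] > 0
        lv = LabelVolume(labels, (1, 1, 1))
        rows = villus_length(lv, BaseSurface(base, (1, 1, 1)))
        ref = dijkstra_reference(labels > 0, base, (1, 1, 1))
        assert rows[0]["length"] == pytest.approx(ref[labels > 0].max(), rel=1e-9)
        assert rows[0]["length"] == pytest.approx(100.0, rel=0.05)

    def test_label_without_base_gets_fallback_flag(self):
        labels = np.zeros((4, 4, 4), np.int32)
        labels[2:4, 1:3, 1:3] = 1
        base = BaseSurface(np.zeros_like(labels, bool), (1, 1, 1))
        rows = villus_length(LabelVolume(labels, (1, 1, 1)), base)
        assert "fallback_base" in rows[0]["flags"]

    def test_geodesic_dominates_euclidean(self, phantom20):
        """Length >= straight-line base-to-farthest distance - one diagonal."""
        spec, _, _, truth_labels, crypt_mask, _ = phantom20
        from villimorph import remove_crypts

        fg = BinaryMask((truth_labels.data > 0) | crypt_mask.data, spec.spacing)
        _, base = remove_crypts(fg, crypt_mask)
        rows = villus_length(truth_labels, base)
        diag = np.linalg.norm(spec.spacing)
        sp = np.asarray(spec.spacing)
        for row in rows[:5]:
            inst = truth_labels.data == row["label_id"]
            bvox = np.argwhere(base.voxels & inst) * sp
            ivox = np.argwhere(inst) * sp
            d = np.linalg.norm(ivox[:, None, :] - bvox[None, :, :], axis=-1)
            euclid = d.min(axis=1).max()
            assert row["length"] >= euclid - diag


class TestVillusVolume:
    def test_single_voxel_arithmetic(self):
        labels = np.zeros((2, 2, 2), np.int32)
        labels[0, 0, 0] = 1
        rows = villus_volume(LabelVolume(labels, (2, 1, 1)))
        assert rows[0]["volume"] == pytest.approx(2.0)

    def test_absent_label_zero_flagged(self):
        labels = np.zeros((2, 2, 2), np.int32)
        labels[0, 0, 0] = 1
        rows = villus_volume(LabelVolume(labels, (1, 1, 1)), label_ids=[1, 2])
        assert rows[1]["volume"] == 0.0 and "empty_label" in rows[1]["flags"]

    def test_phantom_capsules_match_analytic(self, phantom20):
        spec, _, _, truth_labels, _, truth = phantom20
        rows = villus_volume(truth_labels)
        for row in rows:
            assert row["volume"] == pytest.approx(
                truth.volume[row["label_id"] - 1], rel=0.02
            )


class TestVillusSurface:
    def test_empty_label_zero(self):
        labels = np.zeros((3, 3, 3), np.int32)
        labels[1, 1, 1] = 1
        rows = villus_surface(LabelVolume(labels, (1, 1, 1)), method="both")
        assert rows[0]["surface_area_crofton"] > 0

    def test_unknown_method_errors(self):
        labels = LabelVolume(np.ones((2, 2, 2), np.int32), (1, 1, 1))
        with pytest.raises(ValueError, match="method"):
            villus_surface(labels, method="voxel_faces")

    def test_digitized_sphere_both_methods(self):
        r = 20
        n = 45
        z, y, x = np.meshgrid(*[np.arange(n) - n // 2] * 3, indexing="ij")
        sphere = (z * z + y * y + x * x <= r * r).astype(np.int32)
        rows = villus_surface(LabelVolume(sphere, (1, 1, 1)), method="both")
        truth = 4 * np.pi * r * r
        assert rows[0]["surface_area_crofton"] == pytest.approx(truth, rel=0.03)
        assert rows[0]["surface_area_mesh"] == pytest.approx(truth, rel=0.03)

    def test_box_mesh_method(self):
        box = np.zeros((24, 14, 14), np.int32)
        box[2:22, 2:12, 2:12] = 1
        rows = villus_surface(LabelVolume(box, (1, 1, 1)), method="mesh")
        assert rows[0]["surface_area_mesh"] == pytest.approx(1000.0, rel=0.05)

    def test_anisotropic_sphere_crofton(self):
        spacing = (2.0, 0.5, 0.5)
        z = np.arange(-24, 24.01, spacing[0])[:, None, None]
        y = np.arange(-24, 24.01, spacing[1])[None, :, None]
        x = np.arange(-24, 24.01, spacing[2])[None, None, :]
        sphere = (z * z + y * y + x * x <= 400).astype(np.int32)
        rows = villus_surface(LabelVolume(sphere, spacing), method="crofton")
        assert rows[0]["surface_area_crofton"] == pytest.approx(
            4 * np.pi * 400, rel=0.03
        )


class TestFlatness:
    def test_circular_capsule_flatness_one(self, capsule_spec):
        from villimorph.phantoms import rasterize_labels

        labels = rasterize_labels(capsule_spec)
        res = villus_flatness(labels)
        assert res[0].flatness == pytest.approx(1.0, abs=0.1)

    def test_flattened_capsule_a2(self):
        from villimorph.phantoms import PhantomSpec, VillusParams, rasterize_labels

        spec = PhantomSpec(
            volume_shape=(60, 80, 80), spacing=(1.0, 0.5, 0.5),
            villi=[VillusParams((20.0, 20.0), 40.0, 6.0, anisotropy=2.0)],
            crypt_layer_depth=6.0, floor_thickness=4.0,
        )
        labels = rasterize_labels(spec)
        res = villus_flatness(labels)
        assert res[0].flatness == pytest.approx(4.0, rel=0.15)
        # flat axis lies in-plane along y (major_axis_azimuth = 0)
        assert abs(res[0].major_axis[1]) > 0.95

    def test_tiny_instance_flagged(self):
        labels = np.zeros((3, 3, 3), np.int32)
        labels[0, :3, :3] = 1  # 9 voxels
        res = villus_flatness(LabelVolume(labels, (1, 1, 1)))
        assert "too_small" in res[0].flags and np.isnan(res[0].flatness)


class TestRatiosAndEdU:
    def test_ratio_arithmetic(self):
        assert villus_crypt_ratio(300.0, 100.0)["ratio"] == pytest.approx(3.0)
        assert villus_crypt_ratio(100.0, 100.0)["ratio"] == pytest.approx(1.0)

    def test_ratio_undefined_for_nonpositive_depth(self):
        out = villus_crypt_ratio(300.0, 0.0)
        assert np.isnan(out["ratio"]) and "undefined_crypt_depth" in out["flags"]

    def test_point_on_base_is_zero(self):
        epi = np.zeros((5, 3, 3), bool)
        epi[:, 1, 1] = True
        base = np.zeros_like(epi)
        base[0, 1, 1] = True
        out = edu_migration_distance(
            BinaryMask(epi, (1, 1, 1)), BaseSurface(base, (1, 1, 1)),
            PointSet([[0.0, 1.0, 1.0]]),
        )
        assert out["distance"] == 0.0 and out["n_points_used"] == 1

    def test_no_points_flagged(self):
        epi = np.ones((3, 3, 3), bool)
        base = np.zeros_like(epi)
        base[0] = True
        out = edu_migration_distance(
            BinaryMask(epi, (1, 1, 1)), BaseSurface(base, (1, 1, 1)), PointSet([])
        )
        assert out["distance"] == 0.0 and "no_points" in out["flags"]

    def test_off_tissue_point_flagged(self):
        epi = np.zeros((5, 5, 5), bool)
        epi[:, 2, 2] = True
        base = np.zeros_like(epi)
        base[0, 2, 2] = True
        out = edu_migration_distance(
            BinaryMask(epi, (1, 1, 1)), BaseSurface(base, (1, 1, 1)),
            PointSet([[2.0, 0.0, 0.0]]),
        )
        assert "off_tissue_point" in out["flags"]

    def test_bent_tube_max_of_oracle_distances(self):
        epi = np.zeros((12, 12, 3), bool)
        epi[0:10, 1, 1] = True
        epi[9, 1:10, 1] = True
        base = np.zeros_like(epi)
        base[0, 1, 1] = True
        spacing = (1.0, 1.0, 1.0)
        pts_idx = [(3, 1, 1), (7, 1, 1), (9, 4, 1), (9, 8, 1), (0, 1, 1)]
        pts = PointSet(np.asarray(pts_idx, float) * np.asarray(spacing))
        out = edu_migration_distance(BinaryMask(epi, spacing),
                                     BaseSurface(base, spacing), pts)
        ref = dijkstra_reference(epi, base, spacing)
        expected = max(ref[i] for i in pts_idx)
        assert out["distance"] == pytest.approx(expected, rel=1e-9)


class TestOrganoidArea:
    def test_square_area(self):
        mask = np.zeros((20, 20), bool)
        mask[5:15, 5:15] = True
        rows = organoid_area(mask, (1.0, 1.0))
        assert len(rows) == 1 and rows[0]["area"] == pytest.approx(100.0)
        assert not rows[0]["flags"]

    def test_empty_mask_empty_table(self):
        assert organoid_area(np.zeros((5, 5), bool), (1, 1)) == []

    def test_border_touching_flagged(self):
        mask = np.zeros((10, 10), bool)
        mask[0:3, 0:3] = True
        rows = organoid_area(mask, (1.0, 1.0))
        assert "touches_border" in rows[0]["flags"]

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_random_blobs_match_pixel_count(self, seed):
        rng = np.random.default_rng(seed)
        from scipy import ndimage

        mask = ndimage.gaussian_filter(rng.random((40, 40)), 3) > 0.55
        rows = organoid_area(mask, (0.7, 1.3))
        labeled, n = ndimage.label(mask, structure=np.ones((3, 3), bool))
        assert len(rows) == n
        total_pixels = sum(r["area"] for r in rows) / (0.7 * 1.3)
        assert total_pixels == pytest.approx(mask.sum())


class TestScalingLaws:
    def test_spacing_scaling_exact(self):
        """spacing x s scales lengths x s, surfaces x s^2, volumes x s^3."""
        rng = np.random.default_rng(21)
        mask = random_blob_mask(rng, shape=(14, 14, 14), threshold=0.5)
        labels1 = LabelVolume(mask.astype(np.int32), (1.0, 0.5, 0.5))
        s = 2.15
        labels2 = LabelVolume(mask.astype(np.int32),
                              tuple(s * np.array(labels1.spacing)))
        base1 = BaseSurface(_lowest_z(mask), labels1.spacing)
        base2 = BaseSurface(_lowest_z(mask), labels2.spacing)
        l1 = villus_length(labels1, base1)[0]["length"]
        l2 = villus_length(labels2, base2)[0]["length"]
        v1 = villus_volume(labels1)[0]["volume"]
        v2 = villus_volume(labels2)[0]["volume"]
        a1 = villus_surface(labels1, method="both")[0]
        a2 = villus_surface(labels2, method="both")[0]
        assert l2 == pytest.approx(s * l1, rel=1e-9)
        assert v2 == pytest.approx(s**3 * v1, rel=1e-12)
        assert a2["surface_area_crofton"] == pytest.approx(
            s**2 * a1["surface_area_crofton"], rel=1e-9
        )
        assert a2["surface_area_mesh"] == pytest.approx(
            s**2 * a1["surface_area_mesh"], rel=1e-6
        )

    def test_appending_tip_voxels_monotone(self):
        labels = np.zeros((10, 5, 5), np.int32)
        labels[1:6, 2, 2] = 1
        base = np.zeros_like(labels, bool)
        base[1, 2, 2] = True
        lv1 = LabelVolume(labels, (1, 1, 1))
        l1 = villus_length(lv1, BaseSurface(base, (1, 1, 1)))[0]["length"]
        v1 = villus_volume(lv1)[0]["volume"]
        grown = labels.copy()
        grown[6:9, 2, 2] = 1
        lv2 = LabelVolume(grown, (1, 1, 1))
        l2 = villus_length(lv2, BaseSurface(base, (1, 1, 1)))[0]["length"]
        v2 = villus_volume(lv2)[0]["volume"]
        assert l2 >= l1 and v2 >= v1


def _lowest_z(mask):
    base = np.zeros_like(mask)
    zmin = np.argwhere(mask)[:, 0].min()
    base[zmin] = mask[zmin]
    return base
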