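"""Downsampling, foreground extraction, LoG seeding, marker regrowth."""

import numpy as np
import pytest

from villimorph import (
    BinaryMask,
    IntensityVolume,
    LabelVolume,
    SeedingParams,
    downsample,
    foreground_mask,
    generate_seeds,
    upsample_labels,
    watershed_regrow,
)
from villimorph._graph import dijkstra_reference
from conftest import random_blob_mask


def brute_force_partition(mask, seeds, spacing):
    """Assign each mask voxel to the seed label with the smallest geodesic
    distance (ties: smaller label id). Independent heapq-Dijkstra route."""
    ids = np.unique(seeds[seeds > 0])
    fields = [dijkstra_reference(mask, seeds == lab, spacing) for lab in ids]
    out = np.zeros(mask.shape, np.int32)
    stacked = np.stack(fields)
    best = np.argmin(stacked, axis=0)
    reachable = np.isfinite(np.min(stacked, axis=0)) & mask
    out[reachable] = ids[best[reachable]]
    return out


class TestDownsample:
    def test_identity_factors(self):
        vol = IntensityVolume(np.arange(8.0).reshape(2, 2, 2), (2.15, 0.6, 0.6))
        out = downsample(vol, (1, 1, 1))
        np.testing.assert_array_equal(out.data, vol.data)
        assert out.spacing == vol.spacing

    def test_spacing_arithmetic(self):
        vol = IntensityVolume(np.zeros((4, 4, 4)), (2.15, 0.6, 0.6))
        out = downsample(vol, (1, 2, 2))
        assert out.spacing == (2.15, 1.2, 1.2)

    def test_factor_exceeding_axis_errors(self):
        vol = IntensityVolume(np.zeros((2, 4, 4)), (1, 1, 1))
        with pytest.raises(ValueError, match="exceed"):
            downsample(vol, (3, 1, 1))

    def test_mask_majority_vote_brute_force(self):
        rng = np.random.default_rng(2)
        mask = BinaryMask(rng.random((8, 8, 8)) > 0.5, (1, 1, 1))
        out = downsample(mask, (2, 2, 2))
        for k in range(4):
            for j in range(4):
                for i in range(4):
                    block = mask.data[2 * k: 2 * k + 2, 2 * j: 2 * j + 2,
                                      2 * i: 2 * i + 2]
                    assert out.data[k, j, i] == (block.sum() >= 4)


class TestForeground:
    def test_bimodal_image_exact(self):
        rng = np.random.default_rng(0)
        data = rng.normal(10, 1, (12, 12, 12))
        obj = np.zeros((12, 12, 12), bool)
        obj[3:9, 3:9, 3:9] = True
        data[obj] = rng.normal(200, 1, obj.sum())
        mask = foreground_mask(IntensityVolume(data, (1, 1, 1)),
                               min_component_volume=0.0)
        np.testing.assert_array_equal(mask.data, obj)

    def test_constant_image_errors(self):
        with pytest.raises(ValueError, match="no foreground"):
            foreground_mask(IntensityVolume(np.full((4, 4, 4), 7.0), (1, 1, 1)))

    def test_phantom_foreground_jaccard(self, phantom20):
        spec, _, actin, truth_labels, crypt_mask, _ = phantom20
        fg = foreground_mask(actin)
        truth = (truth_labels.data > 0) | crypt_mask.data
        jaccard = (fg.data & truth).sum() / (fg.data | truth).sum()
        assert jaccard >= 0.95


class TestSeeding:
    def test_single_capsule_one_seed(self, capsule_spec, seeding_params):
        from villimorph import generate_phantom
        from villimorph.crypts import remove_crypts

        _, _, labels, crypt_mask, _ = generate_phantom(capsule_spec)
        villus, _ = remove_crypts(
            BinaryMask(labels.data > 0, labels.spacing), crypt_mask
        )
        ds = downsample(villus, seeding_params.downsample_factors)
        seeds = generate_seeds(ds, seeding_params)
        assert len(seeds.label_ids()) == 1
        # seed contained in the capsule
        up = upsample_labels(seeds, villus.shape, villus.spacing)
        assert (labels.data[up.data > 0] > 0).all()

    def test_fused_capsules_two_seeds(self):
        """Two capsules fused over the basal ~10% of their height split into
        one seed inside each capsule's upper shaft."""
        from villimorph.phantoms import PhantomSpec, VillusParams, rasterize_labels

        r, Lc = 6.0, 44.0
        mk = lambda y, tilt: PhantomSpec(
            volume_shape=(60, 120, 60), spacing=(1.0, 0.5, 0.5),
            villi=[VillusParams((y, 15.0), Lc, r, tilt_polar=tilt,
                                tilt_azimuth=0.0)],
            crypt_layer_depth=0.0, floor_thickness=0.0,
        )
        a = rasterize_labels(mk(24.0, 0.0))
        b = rasterize_labels(mk(35.0, 14.0))
        fused = (a.data > 0) | (b.data > 0)
        # fused near the base, separated above
        assert ((a.data > 0) & (b.data > 0))[:10].any()
        assert not ((a.data > 0) & (b.data > 0))[25:].any()
        mask = BinaryMask(fused, (1.0, 0.5, 0.5))
        params = SeedingParams(downsample_factors=(1, 1, 1),
                               sigma_schedule=[6.0, 4.0, 2.5],
                               erosion_step=1.0, max_iterations=6,
                               min_seed_volume=0.2)
        seeds = generate_seeds(mask, params)
        assert len(seeds.label_ids()) == 2
        # one seed strictly inside each capsule, above the fused zone
        memberships = set()
        for lab in seeds.label_ids():
            vox = np.argwhere(seeds.data == lab)
            in_a = (a.data[tuple(vox.T)] > 0).all()
            in_b = (b.data[tuple(vox.T)] > 0).all()
            assert in_a != in_b
            memberships.add("a" if in_a else "b")
        assert memberships == {"a", "b"}

    def test_empty_mask_zero_seeds(self, seeding_params):
        seeds = generate_seeds(
            BinaryMask(np.zeros((8, 8, 8), bool), (1, 1, 1)), seeding_params
        )
        assert seeds.data.max() == 0

    def test_seeds_contained_in_eroded_mask(self, capsule_spec, seeding_params):
        """Anti-monotone erosion: all seeds lie inside the first eroded mask."""
        from villimorph import generate_phantom
        from villimorph.segmentation import _erode_by_radius

        _, _, labels, _, _ = generate_phantom(capsule_spec)
        mask = BinaryMask(labels.data > 0, labels.spacing)
        seeds = generate_seeds(mask, seeding_params)
        eroded1 = _erode_by_radius(mask.data, mask.spacing,
                                   seeding_params.erosion_step)
        assert (eroded1[seeds.data > 0]).all()


class TestWatershedRegrow:
    def test_seeds_equal_components_is_identity(self):
        rng = np.random.default_rng(4)
        from scipy import ndimage

        mask = random_blob_mask(rng, threshold=0.6)
        comp, _ = ndimage.label(mask, structure=np.ones((3, 3, 3), bool))
        seeds = LabelVolume(comp, (1, 1, 1), kind="seed")
        out = watershed_regrow(seeds, BinaryMask(mask, (1, 1, 1)))
        # regrown labels partition identically (ids renumbered by volume)
        for lab in np.unique(comp)[1:]:
            region = comp == lab
            vals = np.unique(out.data[region])
            assert len(vals) == 1 and vals[0] > 0

    def test_tube_split_at_midpoint(self):
        mask = np.zeros((1, 1, 101), bool)
        mask[0, 0, :] = True
        seeds = np.zeros_like(mask, np.int32)
        seeds[0, 0, 10] = 1
        seeds[0, 0, 90] = 2
        out = watershed_regrow(
            LabelVolume(seeds, (1, 1, 1), kind="seed"), BinaryMask(mask, (1, 1, 1))
        )
        boundary = np.where(np.diff(out.data[0, 0]) != 0)[0]
        assert len(boundary) == 1 and abs(boundary[0] - 50) <= 1

    def test_seed_outside_mask_errors(self):
        mask = np.zeros((3, 3, 3), bool)
        mask[1, 1, 1] = True
        seeds = np.zeros_like(mask, np.int32)
        seeds[0, 0, 0] = 1
        with pytest.raises(ValueError, match="inside the mask"):
            watershed_regrow(LabelVolume(seeds, (1, 1, 1), kind="seed"),
                             BinaryMask(mask, (1, 1, 1)))

    def test_no_seeds_all_zero(self):
        mask = np.ones((3, 3, 3), bool)
        out = watershed_regrow(
            LabelVolume(np.zeros((3, 3, 3), np.int32), (1, 1, 1), kind="seed"),
            BinaryMask(mask, (1, 1, 1)),
        )
        assert out.data.max() == 0

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_brute_force_geodesic_partition(self, seed):
        rng = np.random.default_rng(seed)
        shape = tuple(rng.integers(10, 20, 3))
        mask = random_blob_mask(rng, shape=shape, threshold=0.5)
        if not mask.any():
            pytest.skip("degenerate draw")
        vox = np.argwhere(mask)
        n_seeds = min(rng.integers(1, 5), len(vox))
        picks = vox[rng.choice(len(vox), n_seeds, replace=False)]
        seeds = np.zeros(shape, np.int32)
        for i, p in enumerate(picks, start=1):
            seeds[tuple(p)] = i
        spacing = tuple(rng.uniform(0.5, 2.5, 3).round(3))
        out = watershed_regrow(LabelVolume(seeds, spacing, kind="seed"),
                               BinaryMask(mask, spacing))
        ref = brute_force_partition(mask, seeds, spacing)
        # renumbering: compare partitions up to bijection
        assert _same_partition(out.data, ref, mask)

    def test_partition_invariant(self, seeding_params):
        rng = np.random.default_rng(9)
        mask = random_blob_mask(rng, shape=(14, 14, 14), threshold=0.5)
        vox = np.argwhere(mask)
        seeds = np.zeros(mask.shape, np.int32)
        from scipy import ndimage

        comp, n = ndimage.label(mask, structure=np.ones((3, 3, 3), bool))
        for lab in range(1, n + 1):
            p = np.argwhere(comp == lab)[0]
            seeds[tuple(p)] = lab
        out = watershed_regrow(LabelVolume(seeds, (1, 1, 1), kind="seed"),
                               BinaryMask(mask, (1, 1, 1)))
        assert ((out.data > 0) == mask).all()

    def test_determinism(self):
        rng = np.random.default_rng(13)
        mask = random_blob_mask(rng, shape=(16, 16, 16), threshold=0.5)
        vox = np.argwhere(mask)
        seeds = np.zeros(mask.shape, np.int32)
        for i, p in enumerate(vox[:: max(len(vox) // 3, 1)][:3], start=1):
            seeds[tuple(p)] = i
        args = (LabelVolume(seeds, (2, 1, 1), kind="seed"), BinaryMask(mask, (2, 1, 1)))
        np.testing.assert_array_equal(watershed_regrow(*args).data,
                                      watershed_regrow(*args).data)


def _same_partition(a, b, mask):
    """Label grids agree up to a relabeling bijection on mask voxels."""
    av, bv = a[mask], b[mask]
    if ((av > 0) != (bv > 0)).any():
        return False
    mapping = {}
    used = set()
    for x, y in zip(av, bv):
        if x == 0:
            continue
        if x in mapping:
            if mapping[x] != y:
                return False
        else:
            if y in used:
                return False
            mapping[x] = y
            used.add(y)
    return True


class TestUpsample:
    def test_identity(self):
        lab = LabelVolume(np.arange(8).reshape(2, 2, 2), (1, 1, 1))
        out = upsample_labels(lab, (2, 2, 2), (1, 1, 1))
        np.testing.assert_array_equal(out.data, lab.data)

    def test_nearest_neighbour_counts(self):
        lab = np.zeros((2, 2, 2), np.int32)
        lab[0, 0, 0] = 1
        lab[1, 1, 1] = 2
        out = upsample_labels(LabelVolume(lab, (2, 2, 2)), (4, 4, 4), (1, 1, 1))
        assert (out.data == 1).sum() == 8 and (out.data == 2).sum() == 8

    def test_incompatible_shape_errors(self):
        lab = LabelVolume(np.zeros((2, 2, 2), np.int32), (1, 1, 1))
        with pytest.raises(ValueError, match="incompatible"):
            upsample_labels(lab, (1, 2, 2), (1, 1, 1))

    def test_masking_by_foreground(self):
        lab = LabelVolume(np.ones((2, 2, 2), np.int32), (2, 2, 2))
        fg = np.zeros((4, 4, 4), bool)
        fg[0] = True
        out = upsample_labels(lab, (4, 4, 4), (1, 1, 1),
                              foreground=BinaryMask(fg, (1, 1, 1)))
        assert (out.data[0] == 1).all() and (out.data[1:] == 0).all()
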