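"""Shared fixtures: small phantoms and voxel-mask generators."""

from __future__ import annotations

import numpy as np
import pytest

from villimorph import (
    PhantomSpec,
    SeedingParams,
    VillusParams,
    generate_phantom,
    random_phantom_spec,
)

# Seeding parameters matched to the test-scale villus geometry
# (radii ~5-7 μm): erosion per iteration must stay below the narrowest
# half-width (r/a >= 2.5 μm for the flattened cohort).
TEST_SEEDING = dict(
    downsample_factors=(1, 2, 2),
    sigma_schedule=[6.0, 4.0, 2.5],
    erosion_step=1.0,
    max_iterations=6,
    min_seed_volume=1.0,
)

PHANTOM_GEOMETRY = dict(
    spacing=(1.0, 0.5, 0.5),
    radius_range=(5.0, 7.0),
    length_range=(35.0, 50.0),
    clearance=2.0,
    # base plane between voxel centres (z = 12.5 at dz = 1): with the plane
    # exactly on the centre lattice the <=-inclusive inside test systematically
    # adds half a slice of volume to every villus
    crypt_layer_depth=8.5,
    floor_thickness=4.0,
    noise_sd=5.0,
    psf_sigma=(1.0, 0.5, 0.5),
)


@pytest.fixture(scope="session")
def seeding_params() -> SeedingParams:
    return SeedingParams(**TEST_SEEDING)


@pytest.fixture(scope="session")
def phantom20():
    """A 20-villus phantom with its rendered channels and analytic truth."""
    spec = random_phantom_spec(20, rng=np.random.default_rng(42), **PHANTOM_GEOMETRY)
    nuclei, actin, truth_labels, crypt_mask, truth = generate_phantom(spec)
    return spec, nuclei, actin, truth_labels, crypt_mask, truth


@pytest.fixture(scope="session")
def capsule_spec() -> PhantomSpec:
    """One upright capsule (r = 6, L_c = 40) in a small volume."""
    return PhantomSpec(
        volume_shape=(60, 60, 60),
        spacing=(1.0, 0.5, 0.5),
        villi=[VillusParams(base_center=(15.0, 15.0), shaft_length=40.0, radius=6.0)],
        crypt_layer_depth=6.0,
        floor_thickness=4.0,
        noise_sd=0.0,
        psf_sigma=(1.0, 0.5, 0.5),
        rng_seed=0,
    )


def random_blob_mask(rng: np.random.Generator, shape=(16, 16, 16), threshold=0.55):
    """Connected-ish random foreground mask from smoothed noise."""
    from scipy import ndimage

    field = ndimage.gaussian_filter(rng.random(shape), 2.0)
    lo, hi = field.min(), field.max()
    mask = (field - lo) / (hi - lo) > threshold
    return mask


def match_labels_to_truth(labels, truth_labels):
    """Map each recovered label to the truth label it overlaps most."""
    pairs = {}
    for lab in labels.label_ids():
        overlap = truth_labels.data[labels.data == lab]
        overlap = overlap[overlap > 0]
        pairs[int(lab)] = int(np.bincount(overlap).argmax()) if overlap.size else 0
    return pairs
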