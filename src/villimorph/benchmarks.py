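"""Phantom-based validation benchmarks.

Self-contained routines that exercise the whole pipeline against the
synthetic phantoms' analytic ground truth: instance-count recovery under
rendering noise, morphometric accuracy, equivalence of the production
shortest-path engine with a reference Dijkstra, physical-unit scaling laws,
a matched two-condition cohort contrast, and the type-I error calibration of
the cohort statistics. Both the test suite and ``scripts/acceptance.py``
drive these functions.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np
import pandas as pd

from ._graph import dijkstra_reference
from .cohort import compare_groups
from .crypts import BaseSurface, remove_crypts
from .morphometry import (
    villus_flatness,
    villus_length,
    villus_surface,
    villus_volume,
)
from .phantoms import (
    PhantomSpec,
    generate_phantom,
    paired_cohort_specs,
    random_phantom_spec,
)
from .pipeline import segment_villi
from .segmentation import SeedingParams
from .volumes import BinaryMask, LabelVolume

# Seeding parameters matched to the benchmark villus scale (r ~ 5-7 μm):
# erosion per iteration below the narrowest half-width, LoG scales spanning
# the radius range.
BENCH_SEEDING = SeedingParams(
    downsample_factors=(1, 2, 2),
    sigma_schedule=[6.0, 4.0, 2.5],
    erosion_step=1.0,
    max_iterations=6,
    min_seed_volume=1.0,
)

BENCH_GEOMETRY = dict(
    spacing=(1.0, 0.5, 0.5),
    radius_range=(5.0, 7.0),
    length_range=(35.0, 50.0),
    clearance=2.0,
    crypt_layer_depth=8.5,
    floor_thickness=4.0,
    noise_sd=5.0,
    psf_sigma=(1.0, 0.5, 0.5),
)


def bench_phantom(n_villi: int = 20, geometry_seed: int = 42,
                  anisotropy: float = 1.0) -> PhantomSpec:
    """The standard benchmark phantom: n villi at (1, 0.5, 0.5) μm spacing."""
    kw = dict(BENCH_GEOMETRY)
    return random_phantom_spec(
        n_villi, rng=np.random.default_rng(geometry_seed),
        anisotropy_range=(anisotropy, anisotropy), **kw,
    )


def instance_recovery(n_villi: int = 20, n_render_seeds: int = 20,
                      geometry_seed: int = 42, seed0: int = 0) -> dict:
    """Segment the benchmark phantom under ``n_render_seeds`` different
    noise/speckle realisations and count runs recovering the exact
    instance number."""
    spec = bench_phantom(n_villi, geometry_seed)
    counts = []
    for k in range(n_render_seeds):
        s = replace(spec, rng_seed=(seed0 + k) % 2**31)
        _, actin, _, crypt_mask, _ = generate_phantom(s)
        labels, _ = segment_villi(actin, crypt_mask, BENCH_SEEDING)
        counts.append(len(labels.label_ids()))
    exact = sum(c == n_villi for c in counts)
    return {"counts": counts, "n_exact": exact, "n_runs": n_render_seeds,
            "n_villi": n_villi}


def _truth_base(truth_labels: LabelVolume, crypt_mask: BinaryMask):
    fg = BinaryMask((truth_labels.data > 0) | crypt_mask.data, truth_labels.spacing)
    _, base = remove_crypts(fg, crypt_mask)
    return base


def morphometry_accuracy(n_villi: int = 20, geometry_seed: int = 42,
                         render_seed: int = 0) -> dict:
    """Median relative measurement errors against the analytic truth.

    Measurements run on the phantom's exact truth labels, isolating the
    measurement operators from segmentation; the estimated surface of an
    instance includes its flat base cut, so the measured base contact area
    is subtracted before comparing to the (base-excluded) analytic surface.
    """
    spec = replace(bench_phantom(n_villi, geometry_seed), rng_seed=render_seed)
    _, _, truth_labels, crypt_mask, truth = generate_phantom(spec)
    base = _truth_base(truth_labels, crypt_mask)
    lengths = villus_length(truth_labels, base)
    volumes = villus_volume(truth_labels)
    surfaces = villus_surface(truth_labels, method="both")
    dy_dx = spec.spacing[1] * spec.spacing[2]
    errs: dict[str, list[float]] = {k: [] for k in
                                    ("length", "volume", "surface_crofton",
                                     "surface_mesh")}
    for lrow, vrow, srow in zip(lengths, volumes, surfaces):
        i = lrow["label_id"] - 1
        base_area = float((base.voxels & (truth_labels.data == lrow["label_id"])).sum()) * dy_dx
        errs["length"].append(abs(lrow["length"] - truth.length[i]) / truth.length[i])
        errs["volume"].append(abs(vrow["volume"] - truth.volume[i]) / truth.volume[i])
        for key, col in (("surface_crofton", "surface_area_crofton"),
                         ("surface_mesh", "surface_area_mesh")):
            est = srow[col] - base_area
            errs[key].append(abs(est - truth.surface_area[i]) / truth.surface_area[i])
    return {k: float(np.median(v)) for k, v in errs.items()}


def end_to_end_accuracy(n_villi: int = 20, geometry_seed: int = 42,
                        render_seed: int = 0) -> dict:
    """Median relative errors of the full pipeline (Otsu foreground →
    seeding → regrowth → measurement) against analytic truth; recovered
    instances are matched to truth villi by majority voxel overlap."""
    spec = replace(bench_phantom(n_villi, geometry_seed), rng_seed=render_seed)
    _, actin, truth_labels, crypt_mask, truth = generate_phantom(spec)
    labels, base = segment_villi(actin, crypt_mask, BENCH_SEEDING)
    lengths = villus_length(labels, base)
    volumes = villus_volume(labels)
    surfaces = villus_surface(labels, method="crofton")
    dy_dx = spec.spacing[1] * spec.spacing[2]
    errs: dict[str, list[float]] = {"length": [], "volume": [], "surface_crofton": []}
    for lrow, vrow, srow in zip(lengths, volumes, surfaces):
        lab = lrow["label_id"]
        overlap = truth_labels.data[labels.data == lab]
        overlap = overlap[overlap > 0]
        if not overlap.size:
            continue
        i = int(np.bincount(overlap).argmax()) - 1
        base_area = float((base.voxels & (labels.data == lab)).sum()) * dy_dx
        errs["length"].append(abs(lrow["length"] - truth.length[i]) / truth.length[i])
        errs["volume"].append(abs(vrow["volume"] - truth.volume[i]) / truth.volume[i])
        est = srow["surface_area_crofton"] - base_area
        errs["surface_crofton"].append(
            abs(est - truth.surface_area[i]) / truth.surface_area[i])
    return {k: float(np.median(v)) for k, v in errs.items()} | {
        "n_instances": len(lengths)}


def flatness_recovery(n_villi: int = 6, geometry_seed: int = 7,
                      anisotropy: float = 2.0) -> dict:
    """Median recovered flatness of flattened (a = 2) villi; target a² = 4."""
    spec = bench_phantom(n_villi, geometry_seed, anisotropy=anisotropy)
    _, _, truth_labels, _, _ = generate_phantom(spec)
    res = villus_flatness(truth_labels)
    vals = [r.flatness for r in res if np.isfinite(r.flatness)]
    return {"median_flatness": float(np.median(vals)), "target": anisotropy**2,
            "n": len(vals)}


def _random_blob(rng, shape, threshold=0.5):
    from scipy import ndimage

    field = ndimage.gaussian_filter(rng.random(shape), 2.0)
    lo, hi = field.min(), field.max()
    return (field - lo) / max(hi - lo, 1e-12) > threshold


def oracle_equivalence(n_masks: int = 50, seed: int = 0) -> dict:
    """Production shortest-path engine vs reference heapq Dijkstra.

    For each random mask (≤ 32³, ≤ 4 seeds): the marker-regrowth partition
    must equal the brute-force nearest-seed geodesic partition voxel for
    voxel (up to label renumbering), and the geodesic field must match the
    reference to 1e-9 relative.
    """
    from .morphometry import geodesic_distance
    from .segmentation import watershed_regrow

    rng = np.random.default_rng(seed)
    partition_ok = 0
    max_rel_dev = 0.0
    for _ in range(n_masks):
        shape = tuple(rng.integers(10, 24, 3))
        mask = _random_blob(rng, shape)
        if not mask.any():
            partition_ok += 1
            continue
        vox = np.argwhere(mask)
        n_seeds = int(min(rng.integers(1, 5), len(vox)))
        seeds = np.zeros(shape, np.int32)
        for i, p in enumerate(vox[rng.choice(len(vox), n_seeds, replace=False)], 1):
            seeds[tuple(p)] = i
        spacing = tuple(rng.uniform(0.5, 2.5, 3).round(3))
        out = watershed_regrow(LabelVolume(seeds, spacing, kind="seed"),
                               BinaryMask(mask, spacing))
        ids = np.unique(seeds[seeds > 0])
        fields = np.stack([dijkstra_reference(mask, seeds == lab, spacing)
                           for lab in ids])
        ref = np.zeros(shape, np.int32)
        reach = mask & np.isfinite(fields.min(axis=0))
        ref[reach] = ids[np.argmin(fields, axis=0)[reach]]
        if _same_partition(out.data, ref, mask):
            partition_ok += 1
        # geodesic field vs reference from the first seed set
        field = geodesic_distance(mask, seeds == ids[0], spacing) \
            if (mask & (seeds == ids[0])).any() else None
        if field is not None:
            rf = dijkstra_reference(mask, seeds == ids[0], spacing)
            fin = mask & np.isfinite(rf) & (rf > 0)
            if fin.any():
                dev = np.max(np.abs(field[fin] - rf[fin]) / rf[fin])
                max_rel_dev = max(max_rel_dev, float(dev))
    return {"partition_ok": partition_ok, "n_masks": n_masks,
            "geodesic_max_rel_dev": max_rel_dev}


def _same_partition(a, b, mask):
    av, bv = a[mask], b[mask]
    if ((av > 0) != (bv > 0)).any():
        return False
    mapping: dict[int, int] = {}
    used: set[int] = set()
    for x, y in zip(av, bv):
        if x == 0:
            continue
        if x in mapping:
            if mapping[x] != y:
                return False
        elif y in used:
            return False
        else:
            mapping[x] = y
            used.add(y)
    return True


def scaling_laws(seed: int = 21, s: float = 2.15) -> dict:
    """Max relative deviation from exact s / s² / s³ scaling of
    length / surface / volume when the spacing is scaled by s."""
    rng = np.random.default_rng(seed)
    mask = _random_blob(rng, (14, 14, 14))
    zmin = np.argwhere(mask)[:, 0].min()
    base_vox = np.zeros_like(mask)
    base_vox[zmin] = mask[zmin]
    devs = []
    sp1 = (1.0, 0.5, 0.5)
    sp2 = tuple(s * np.array(sp1))
    l1 = villus_length(LabelVolume(mask.astype(np.int32), sp1),
                       BaseSurface(base_vox, sp1))[0]["length"]
    l2 = villus_length(LabelVolume(mask.astype(np.int32), sp2),
                       BaseSurface(base_vox, sp2))[0]["length"]
    devs.append(abs(l2 - s * l1) / (s * l1))
    v1 = villus_volume(LabelVolume(mask.astype(np.int32), sp1))[0]["volume"]
    v2 = villus_volume(LabelVolume(mask.astype(np.int32), sp2))[0]["volume"]
    devs.append(abs(v2 - s**3 * v1) / (s**3 * v1))
    a1 = villus_surface(LabelVolume(mask.astype(np.int32), sp1), method="both")[0]
    a2 = villus_surface(LabelVolume(mask.astype(np.int32), sp2), method="both")[0]
    for col in ("surface_area_crofton", "surface_area_mesh"):
        devs.append(abs(a2[col] - s**2 * a1[col]) / (s**2 * a1[col]))
    return {"max_rel_dev": float(max(devs))}


def cohort_contrast(n_phantoms: int = 5, villi_per_phantom: int = 4,
                    seed: int = 0, length_scale: float = 1.5,
                    flattening: float = 2.0) -> dict:
    """Matched nulliparous-vs-lactation synthetic cohort through the full
    pipeline: recovered mean length ratio, Tukey-adjusted p for length and
    Welch p for flatness."""
    ctrl_specs, lact_specs = paired_cohort_specs(
        n_phantoms, villi_per_phantom, rng=np.random.default_rng(seed),
        length_scale=length_scale, flattening=flattening,
    )
    rows = []
    for group, specs in (("nulliparous", ctrl_specs), ("lactation", lact_specs)):
        for i, spec in enumerate(specs):
            _, actin, _, crypt_mask, _ = generate_phantom(spec)
            labels, base = segment_villi(actin, crypt_mask, BENCH_SEEDING)
            lengths = villus_length(labels, base)
            flats = {r.label_id: r.flatness for r in villus_flatness(labels)}
            for lrow in lengths:
                rows.append({
                    "group": group, "mouse_id": f"{group}_{i}",
                    "length": lrow["length"],
                    "flatness": flats.get(lrow["label_id"], np.nan),
                })
    table = pd.DataFrame(rows)
    means = table.groupby("group")["length"].mean()
    ratio = float(means["lactation"] / means["nulliparous"])
    rep_len = compare_groups(table, "length", design="multi_group")
    rep_flat = compare_groups(table, "flatness", design="two_group")
    flat_means = table.groupby("group")["flatness"].mean()
    return {
        "length_ratio": ratio,
        "length_tukey_p": rep_len["tukey"][0]["p_adj"],
        "flatness_p": rep_flat["p"],
        "flatness_means": {g: float(v) for g, v in flat_means.items()},
        "n_villi": {g: int((table.group == g).sum()) for g in means.index},
    }


def anova_type1_calibration(n_sim: int = 1000, seed: int = 123,
                            n_per_group: int = 12, alpha: float = 0.05) -> dict:
    """Empirical rejection rate of the cohort ANOVA under the null."""
    rng = np.random.default_rng(seed)
    groups = np.repeat(["a", "b", "c"], n_per_group)
    mice = [f"m{i}" for i in range(3 * n_per_group)]
    rejections = 0
    for _ in range(n_sim):
        df = pd.DataFrame({
            "group": groups, "mouse_id": mice,
            "length": rng.normal(0.0, 1.0, 3 * n_per_group),
        })
        rep = compare_groups(df, "length", design="multi_group", post_hoc=False)
        rejections += rep["p"] < alpha
    return {"rate": rejections / n_sim, "n_sim": n_sim, "alpha": alpha}
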