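"""Per-instance physical measurements on segmented villi.

Length is the maximum of a distance map started at the base of the villus.
The map is geodesic — shortest paths confined to the instance on the
26-connected voxel graph with physical edge lengths — because for tilted or
curved villi an unconstrained Euclidean map would cut through the lumen and
under-estimate length. Volume is voxel count times voxel volume. Surface area
uses a Crofton-formula estimator with 13 discrete directions on the
anisotropic grid (direction weights from the spherical Voronoi partition of
the 26 unit directions), with a triangulated half-level-set (marching-cubes)
area as the cross-check method.

Flatness quantifies the elliptical cross-section of expanded villi: the
instance is sliced perpendicular to its principal axis and the median
square-root eigenvalue ratio of the per-slice 2D covariance is reported
(equal to the cross-section axis ratio; a capsule flattened with
area-preserving anisotropy ``a`` has axis ratio ``a²``).

Degenerate instances are flagged, never raised: cohort tables keep one row
per label.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
import trimesh
from scipy import ndimage
from scipy.optimize import nnls
from skimage.measure import marching_cubes, mesh_surface_area

from ._graph import geodesic_field
from .crypts import BaseSurface
from .volumes import BinaryMask, LabelVolume, PointSet, VillusMorphometry

logger = logging.getLogger(__name__)

_STRUCT8_2D = np.ones((3, 3), dtype=bool)


# ---------------------------------------------------------------------------
# Distance maps and length


def geodesic_distance(instance: np.ndarray, sources: np.ndarray, spacing) -> np.ndarray:
    """Within-instance shortest-path distance field in μm.

    ``instance`` and ``sources`` are boolean grids; sources must be nonempty
    and inside the instance. Source voxels get 0; instance voxels unreachable
    from every source get +inf; background is +inf.
    """
    return geodesic_field(instance, sources, spacing)


def villus_length(labels: LabelVolume, base: BaseSurface, spacing=None) -> list[dict]:
    """Per-villus length: maximum geodesic distance from the base surface.

    A label with no base voxels falls back to its own lowest-z voxels as the
    source set and is flagged ``fallback_base``.
    """
    spacing = labels.spacing if spacing is None else tuple(spacing)
    rows: list[dict] = []
    data = labels.data
    for lab in labels.label_ids():
        instance = data == lab
        sources = instance & base.voxels
        flags = set()
        if not sources.any():
            flags.add("fallback_base")
            zmin = int(np.argwhere(instance)[:, 0].min())
            sources = np.zeros_like(instance)
            sources[zmin] = instance[zmin]
        field = geodesic_field(instance, sources, spacing)
        finite = field[instance & np.isfinite(field)]
        if finite.size < instance.sum():
            flags.add("disconnected_from_base")
        rows.append({"label_id": int(lab), "length": float(finite.max()),
                     "flags": flags})
    return rows


# ---------------------------------------------------------------------------
# Volume


def villus_volume(labels: LabelVolume, spacing=None, label_ids=None) -> list[dict]:
    """Per-villus volume: voxel count × dz·dy·dx."""
    spacing = labels.spacing if spacing is None else tuple(spacing)
    voxvol = float(np.prod(spacing))
    counts = np.bincount(labels.data.ravel())
    ids = labels.label_ids() if label_ids is None else np.asarray(label_ids)
    rows = []
    for lab in ids:
        n = int(counts[lab]) if lab < len(counts) else 0
        flags = set() if n else {"empty_label"}
        rows.append({"label_id": int(lab), "volume": n * voxvol, "flags": flags})
    return rows


# ---------------------------------------------------------------------------
# Surface area


def _fibonacci_sphere(m: int = 800) -> np.ndarray:
    """Deterministic near-uniform unit directions (Fibonacci lattice)."""
    i = np.arange(m) + 0.5
    polar = np.arccos(1.0 - 2.0 * i / m)
    azim = np.pi * (1.0 + np.sqrt(5.0)) * i
    return np.stack(
        [np.cos(polar), np.sin(polar) * np.cos(azim), np.sin(polar) * np.sin(azim)],
        axis=1,
    )


def crofton_directions(spacing) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """The 13 grid directions with physical periods and calibrated weights.

    Directions are the 13 half-neighbourhood offsets of 26-connectivity,
    scaled by the spacing. The discrete Crofton estimator is exact only if
    the weighted directional response Σ_k w_k |n·u_k| equals 1/2 for every
    surface normal n; on anisotropic grids the classical spherical-partition
    weights leave an orientation-dependent bias of several percent, so the
    weights here are calibrated once per direction set by non-negative least
    squares against that condition over a dense uniform normal sampling.
    The weights depend on spacing only through the unit directions, so
    uniformly scaling the spacing leaves them bit-identical (the spacing → s²
    surface-scaling law is exact).
    """
    offsets = np.array(
        [off for off in itertools.product((-1, 0, 1), repeat=3) if off > (0, 0, 0)],
        dtype=float,
    )
    vecs = offsets * np.asarray(spacing, dtype=float)
    periods = np.linalg.norm(vecs, axis=1)
    units = vecs / periods[:, None]
    normals = _fibonacci_sphere()
    response = np.abs(normals @ units.T)
    weights, _ = nnls(response, np.full(len(normals), 0.5))
    return offsets.astype(int), periods, weights


def _crofton_area(binary: np.ndarray, spacing) -> float:
    """Crofton estimate S = 2 Σ_k w_k (v/d_k) N_k on a zero-padded crop.

    ``N_k`` counts membership transitions between voxels one step apart along
    direction k (lines parallel to k sample the volume with period ``d_k``
    and cross-sectional area ``v/d_k`` per line, so each transition
    contributes one line–surface intersection; Cauchy's projection formula
    supplies the factor 2 over hemisphere weights).
    """
    binary = np.pad(binary, 1)
    offsets, periods, weights = crofton_directions(spacing)
    voxvol = float(np.prod(spacing))
    total = 0.0
    for off, d, w in zip(offsets, periods, weights):
        sl_a, sl_b = [], []
        for size, o in zip(binary.shape, off):
            if o > 0:
                sl_a.append(slice(0, size - o))
                sl_b.append(slice(o, size))
            elif o < 0:
                sl_a.append(slice(-o, size))
                sl_b.append(slice(0, size + o))
            else:
                sl_a.append(slice(None))
                sl_b.append(slice(None))
        n_trans = int(np.count_nonzero(binary[tuple(sl_a)] != binary[tuple(sl_b)]))
        total += w * (voxvol / d) * n_trans
    return 2.0 * total


def _mesh_area(binary: np.ndarray, spacing, smooth_iterations: int = 20) -> float:
    """Triangulated area of the half-level set (marching cubes).

    The raw binary isosurface is a chamfered staircase whose area
    over-estimates smooth surfaces by up to ~10%, so the mesh is relaxed with
    Taubin's non-shrinking two-step filter (λ = 0.5, ν = 0.6) before
    measuring; flat faces are fixed points of the filter, so boxes stay
    boxes.
    """
    padded = np.pad(binary, 1).astype(np.float64)
    verts, faces, _, _ = marching_cubes(padded, level=0.5, spacing=tuple(spacing))
    if smooth_iterations:
        mesh = trimesh.Trimesh(vertices=verts, faces=faces, process=False)
        trimesh.smoothing.filter_taubin(mesh, lamb=0.5, nu=0.6,
                                        iterations=smooth_iterations)
        return float(mesh.area)
    return float(mesh_surface_area(verts, faces))


def villus_surface(labels: LabelVolume, spacing=None, method: str = "crofton") -> list[dict]:
    """Per-villus surface area in μm² (``method``: crofton | mesh | both)."""
    if method not in ("crofton", "mesh", "both"):
        raise ValueError(f"unknown surface method {method!r}")
    spacing = labels.spacing if spacing is None else tuple(spacing)
    data = labels.data
    slices = ndimage.find_objects(data)
    rows = []
    for lab in labels.label_ids():
        sl = slices[lab - 1]
        binary = data[sl] == lab
        row: dict = {"label_id": int(lab), "flags": set()}
        if method in ("crofton", "both"):
            row["surface_area_crofton"] = _crofton_area(binary, spacing)
        if method in ("mesh", "both"):
            row["surface_area_mesh"] = _mesh_area(binary, spacing)
        main = "surface_area_crofton" if method != "mesh" else "surface_area_mesh"
        row["surface_area"] = row[main]
        row["surface_method"] = method if method != "both" else "crofton"
        rows.append(row)
    return rows


# ---------------------------------------------------------------------------
# Flatness


@dataclass
class FlatnessResult:
    label_id: int
    flatness: float           # median per-slice sqrt(λ_major / λ_minor), ≥ 1
    major_axis: np.ndarray    # volume-weighted mean major cross-section axis (z,y,x)
    flags: set


def villus_flatness(
    labels: LabelVolume,
    spacing=None,
    slab_thickness: float | None = None,
    min_voxels: int = 10,
    min_slab_voxels: int = 10,
) -> list[FlatnessResult]:
    """Cross-sectional flatness per instance.

    Slices each instance by slabs perpendicular to its principal (long) axis,
    takes the 2D covariance eigenvalues of voxel positions per slab (physical
    units) and reports the median axis ratio ``sqrt(λ_major/λ_minor)``.
    Instances with fewer than ``min_voxels`` voxels, or line-like instances
    with no usable slab, are flagged with NaN flatness.
    """
    spacing = np.asarray(labels.spacing if spacing is None else spacing, dtype=float)
    if slab_thickness is None:
        slab_thickness = 2.0 * float(spacing.max())
    results: list[FlatnessResult] = []
    for lab in labels.label_ids():
        idx = np.argwhere(labels.data == lab)
        flags: set = set()
        if len(idx) < min_voxels:
            results.append(FlatnessResult(int(lab), float("nan"), np.full(3, np.nan),
                                          {"too_small"}))
            continue
        pts = idx * spacing
        centred = pts - pts.mean(axis=0)
        cov = centred.T @ centred / len(pts)
        evals, evecs = np.linalg.eigh(cov)
        u = evecs[:, -1]  # principal (long) axis
        e1 = evecs[:, 1]
        e2 = evecs[:, 0]
        t = centred @ u
        bins = np.floor((t - t.min()) / slab_thickness).astype(int)
        ratios = []
        majors = []
        weights = []
        for b in np.unique(bins):
            sel = bins == b
            if int(sel.sum()) < min_slab_voxels:
                continue
            q = np.stack([centred[sel] @ e1, centred[sel] @ e2], axis=1)
            qc = q - q.mean(axis=0)
            c2 = qc.T @ qc / len(qc)
            ev2, evec2 = np.linalg.eigh(c2)
            if ev2[0] <= 1e-12:
                continue
            ratios.append(float(np.sqrt(ev2[1] / ev2[0])))
            major3 = evec2[0, 1] * e1 + evec2[1, 1] * e2
            majors.append(major3)
            weights.append(int(sel.sum()))
        if not ratios:
            results.append(FlatnessResult(int(lab), float("nan"), np.full(3, np.nan),
                                          {"degenerate"}))
            continue
        majors_arr = np.stack(majors)
        # axis sign is arbitrary; align to the first slab before averaging
        signs = np.sign(majors_arr @ majors_arr[0])
        signs[signs == 0] = 1.0
        mean_major = (majors_arr * (np.asarray(weights) * signs)[:, None]).sum(axis=0)
        norm = np.linalg.norm(mean_major)
        mean_major = mean_major / norm if norm > 0 else np.full(3, np.nan)
        results.append(FlatnessResult(int(lab), float(np.median(ratios)), mean_major, flags))
    return results


# ---------------------------------------------------------------------------
# Ratios, EdU, organoids


def villus_crypt_ratio(villus_length_um: float, crypt_depth_um: float) -> dict:
    """Villus height over crypt depth (dimensionless)."""
    if not crypt_depth_um > 0 or not np.isfinite(crypt_depth_um):
        return {"ratio": float("nan"), "flags": {"undefined_crypt_depth"}}
    return {"ratio": float(villus_length_um) / float(crypt_depth_um), "flags": set()}


def edu_migration_distance(
    epithelium: BinaryMask,
    base: BaseSurface,
    points: PointSet,
    spacing=None,
) -> dict:
    """Migration distance: geodesic distance from the crypt base to the
    farthest labelled cell.

    Points (physical μm) are snapped to their nearest epithelium voxel; a
    point farther than one voxel diagonal from any epithelium voxel is
    flagged off-tissue and ignored. With no usable points the distance is 0
    with a ``no_points`` flag.
    """
    spacing = np.asarray(epithelium.spacing if spacing is None else spacing, dtype=float)
    diag = float(np.linalg.norm(spacing))
    flags: set = set()
    if len(points) == 0:
        return {"distance": 0.0, "farthest_point": None, "flags": {"no_points"},
                "n_points_used": 0}
    snapped: list[tuple[int, int, int]] = []
    shape = epithelium.shape
    for p in points.points:
        c = np.rint(p / spacing).astype(int)
        best = None
        best_d = np.inf
        for off in itertools.product((-1, 0, 1), repeat=3):
            q = c + off
            if not all(0 <= q[i] < shape[i] for i in range(3)):
                continue
            if not epithelium.data[tuple(q)]:
                continue
            d = float(np.linalg.norm(q * spacing - p))
            if d < best_d:
                best, best_d = tuple(q), d
        if best is None or best_d > diag:
            flags.add("off_tissue_point")
            continue
        snapped.append(best)  # type: ignore[arg-type]
    if not snapped:
        flags.add("no_points")
        return {"distance": 0.0, "farthest_point": None, "flags": flags, "n_points_used": 0}
    field = geodesic_field(epithelium.data, base.voxels & epithelium.data, spacing)
    dists = [field[s] for s in snapped]
    finite = [(d, s) for d, s in zip(dists, snapped) if np.isfinite(d)]
    if not finite:
        flags.add("unreachable_points")
        return {"distance": 0.0, "farthest_point": None, "flags": flags, "n_points_used": 0}
    dmax, smax = max(finite, key=lambda ds: ds[0])
    return {
        "distance": float(dmax),
        "farthest_point": tuple(np.asarray(smax) * spacing),
        "flags": flags,
        "n_points_used": len(finite),
    }


def organoid_area(mask2d: np.ndarray, pixel_spacing) -> list[dict]:
    """Per-object 2D cross-section areas in μm² (8-connected components).

    Components touching the image border are flagged (their area is
    truncated by the field of view).
    """
    mask2d = np.asarray(mask2d, dtype=bool)
    if mask2d.ndim != 2:
        raise ValueError("organoid mask must be 2D")
    dy, dx = (float(s) for s in pixel_spacing)
    labeled, n = ndimage.label(mask2d, structure=_STRUCT8_2D)
    rows = []
    for lab in range(1, n + 1):
        comp = labeled == lab
        border = bool(comp[0].any() or comp[-1].any() or comp[:, 0].any() or comp[:, -1].any())
        rows.append({
            "label_id": lab,
            "area": float(comp.sum()) * dy * dx,
            "flags": {"touches_border"} if border else set(),
        })
    return rows


# ---------------------------------------------------------------------------
# Batch measurement


def measure_villi(
    labels: LabelVolume,
    base: BaseSurface,
    sample_id: str = "sample",
    surface_method: str = "crofton",
) -> list[VillusMorphometry]:
    """All per-villus measurements for one labelled volume.

    Base contact area is approximated as the lateral (dy·dx) footprint of the
    instance's base voxels.
    """
    spacing = labels.spacing
    lengths = {r["label_id"]: r for r in villus_length(labels, base)}
    volumes = {r["label_id"]: r for r in villus_volume(labels)}
    surfaces = {r["label_id"]: r for r in villus_surface(labels, method=surface_method)}
    flatnesses = {r.label_id: r for r in villus_flatness(labels)}
    dy_dx = spacing[1] * spacing[2]
    rows = []
    for lab in labels.label_ids():
        lab = int(lab)
        n_base = int((base.voxels & (labels.data == lab)).sum())
        flags = set()
        flags |= lengths[lab]["flags"]
        flags |= volumes[lab]["flags"]
        flags |= surfaces[lab]["flags"]
        flags |= flatnesses[lab].flags
        rows.append(VillusMorphometry(
            sample_id=sample_id,
            label_id=lab,
            length=lengths[lab]["length"],
            volume=volumes[lab]["volume"],
            surface_area=surfaces[lab]["surface_area"],
            flatness=flatnesses[lab].flatness,
            base_contact_area=n_base * dy_dx,
            flags=frozenset(flags),
        ))
    return rows
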