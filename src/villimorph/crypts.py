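"""Crypt masking: sparse slice annotations → 3D crypt mask → villus base.

The crypt region is annotated manually on a few 2D slices and interpolated to
cover the volume. Interpolation is shape-based: each annotated slice becomes a
signed 2D Euclidean distance field (negative inside the region), unannotated
slices between two annotated ones take the z-linear interpolation of the
bracketing fields, and the mask is the field's non-positive set. Slices
outside the annotated range copy the nearest annotated field. This handles
region growth/shrink between slices gracefully and is fully deterministic.

Removing the crypt mask from the tissue foreground leaves the villi; the
voxels of the remainder that touch the crypt mask (26-adjacency) form the
villus base surface, the source set for all length measurements.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.draw import polygon2mask

from ._graph import geodesic_field
from .volumes import BinaryMask, LabelVolume

logger = logging.getLogger(__name__)

_STRUCT26 = np.ones((3, 3, 3), dtype=bool)


@dataclass
class SliceAnnotation:
    """One manually drawn crypt region on one z-slice.

    ``region`` is either a closed simple polygon in physical (y, x) μm
    coordinates, shape (n, 2), or a pre-rasterized 2D boolean mask.
    """

    z_index: int
    region: np.ndarray

    def rasterize(self, shape_yx: tuple[int, int], spacing_yx: tuple[float, float]) -> np.ndarray:
        region = np.asarray(self.region)
        if region.dtype == bool:
            if region.shape != shape_yx:
                raise ValueError(
                    f"annotation mask shape {region.shape} != slice shape {shape_yx}"
                )
            return region
        if region.ndim != 2 or region.shape[1] != 2 or region.shape[0] < 3:
            raise ValueError("polygon must be an (n>=3, 2) array of (y, x) μm vertices")
        _check_simple_polygon(region)
        # polygon in pixel units; even-odd rule at pixel centres
        verts_px = region / np.asarray(spacing_yx, dtype=float)
        return polygon2mask(shape_yx, verts_px)


def _check_simple_polygon(verts: np.ndarray) -> None:
    """Reject self-intersecting polygons (O(n²) segment test; annotations are small)."""
    n = len(verts)
    segs = [(verts[i], verts[(i + 1) % n]) for i in range(n)]

    def cross2(a, b) -> float:
        return float(a[0] * b[1] - a[1] * b[0])

    def intersects(p1, p2, p3, p4) -> bool:
        d1 = cross2(p4 - p3, p1 - p3)
        d2 = cross2(p4 - p3, p2 - p3)
        d3 = cross2(p2 - p1, p3 - p1)
        d4 = cross2(p2 - p1, p4 - p1)
        return ((d1 > 0) != (d2 > 0)) and ((d3 > 0) != (d4 > 0))

    for i in range(n):
        for j in range(i + 2, n):
            if i == 0 and j == n - 1:
                continue  # shared vertex with the closing segment
            if intersects(*segs[i], *segs[j]):
                raise ValueError("annotation polygon is self-intersecting")


def _signed_distance_2d(mask: np.ndarray, spacing_yx) -> np.ndarray:
    """Signed EDT in μm: negative inside, positive outside."""
    spacing_yx = np.asarray(spacing_yx, dtype=float)
    if mask.any():
        outside = ndimage.distance_transform_edt(~mask, sampling=spacing_yx)
        inside = ndimage.distance_transform_edt(mask, sampling=spacing_yx)
        return outside - inside
    # empty region: strictly positive everywhere
    return np.full(mask.shape, np.max(mask.shape * spacing_yx) + 1.0)


def interpolate_annotations(
    annos: list[SliceAnnotation],
    shape: tuple[int, int, int],
    spacing,
) -> BinaryMask:
    """Shape-based interpolation of per-slice crypt annotations to 3D.

    Multiple annotations on the same slice are unioned before interpolation.
    """
    if not annos:
        raise ValueError("at least one slice annotation is required")
    nz, ny, nx = shape
    spacing = tuple(float(s) for s in spacing)
    by_slice: dict[int, np.ndarray] = {}
    for a in annos:
        if not 0 <= a.z_index < nz:
            raise ValueError(f"annotation z_index {a.z_index} outside volume (nz={nz})")
        m = a.rasterize((ny, nx), spacing[1:])
        by_slice[a.z_index] = by_slice.get(a.z_index, np.zeros((ny, nx), bool)) | m

    zs = sorted(by_slice)
    fields = {z: _signed_distance_2d(by_slice[z], spacing[1:]) for z in zs}

    out = np.zeros(shape, dtype=bool)
    for k in range(nz):
        if k <= zs[0]:
            f = fields[zs[0]]
        elif k >= zs[-1]:
            f = fields[zs[-1]]
        elif k in fields:
            f = fields[k]
        else:
            hi = min(z for z in zs if z > k)
            lo = max(z for z in zs if z < k)
            t = (k - lo) / (hi - lo)
            f = (1.0 - t) * fields[lo] + t * fields[hi]
        out[k] = f <= 0.0
    return BinaryMask(out, spacing)


def read_annotations(path) -> list[SliceAnnotation]:
    """Load crypt annotations from JSON polygons or a sparse mask TIFF.

    JSON: a list of ``{"z": int, "polygon": [[y, x], ...]}`` objects with
    polygon vertices in μm. TIFF: a multi-page stack whose non-empty pages
    are per-slice boolean masks.
    """
    import json
    from pathlib import Path

    path = Path(path)
    if path.suffix.lower() == ".json":
        payload = json.loads(path.read_text())
        return [SliceAnnotation(int(a["z"]), np.asarray(a["polygon"], dtype=float))
                for a in payload]
    import tifffile

    stack = tifffile.imread(path)
    if stack.ndim == 2:
        stack = stack[np.newaxis]
    return [SliceAnnotation(z, page > 0)
            for z, page in enumerate(stack) if (page > 0).any()]


@dataclass
class BaseSurface:
    """Voxels on the villus side of the villus–crypt interface."""

    voxels: np.ndarray  # boolean grid
    spacing: tuple[float, float, float]

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels, dtype=bool)

    @property
    def n_voxels(self) -> int:
        return int(self.voxels.sum())


def remove_crypts(foreground: BinaryMask, crypt_mask: BinaryMask) -> tuple[BinaryMask, BaseSurface]:
    """Subtract the crypt mask from the tissue foreground and find the base.

    The base is every remaining foreground voxel 26-adjacent to a crypt-mask
    voxel. If the crypt mask is empty, the z = 0 face of the foreground is
    used as the base (logged as a fallback; useful for cropped stacks and
    phantoms without a crypt layer).
    """
    if foreground.shape != crypt_mask.shape:
        raise ValueError(f"shape mismatch: {foreground.shape} vs {crypt_mask.shape}")
    if foreground.spacing != crypt_mask.spacing:
        raise ValueError(f"spacing mismatch: {foreground.spacing} vs {crypt_mask.spacing}")
    villus = foreground.data & ~crypt_mask.data
    if crypt_mask.data.any():
        near_crypt = ndimage.binary_dilation(crypt_mask.data, structure=_STRUCT26)
        base = villus & near_crypt
    else:
        logger.info("empty crypt mask: using the z=0 foreground face as villus base")
        base = np.zeros_like(villus)
        base[0] = villus[0]
    return BinaryMask(villus, foreground.spacing), BaseSurface(base, foreground.spacing)


def crypt_depth(crypt_labels: LabelVolume, opening: BaseSurface) -> list[dict]:
    """Per-crypt depth: maximum geodesic distance from the crypt's opening.

    ``opening`` marks the luminal-side voxels of the crypt mask (the analogue
    of the villus base on the crypt side). A crypt whose label contains no
    opening voxel yields a flagged row with NaN depth rather than an error.
    """
    rows: list[dict] = []
    data = crypt_labels.data
    for lab in crypt_labels.label_ids():
        instance = data == lab
        sources = instance & opening.voxels
        if not sources.any():
            rows.append({"label_id": int(lab), "depth": float("nan"),
                         "flags": "no_opening"})
            continue
        field = geodesic_field(instance, sources, crypt_labels.spacing)
        finite = field[instance & np.isfinite(field)]
        rows.append({"label_id": int(lab), "depth": float(finite.max()), "flags": ""})
    return rows
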