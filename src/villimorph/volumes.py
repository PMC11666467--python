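"""Volume containers and file I/O.

All grids use axis order ``(z, y, x)`` with the slice index leading, matching
slice-major confocal acquisition. Physical voxel spacing ``(dz, dy, dx)`` in
micrometres is mandatory on every container: confocal stacks are strongly
anisotropic (a z-step of ~2 μm against sub-micron pixels is typical) and every
downstream measurement is in physical units. The physical coordinate of voxel
``(k, j, i)`` is ``(k*dz, j*dy, i*dx)`` (voxel centres, 0-based).

Volumes are stored as OME-TIFF with spacing in the OME-XML metadata; plain
ImageJ-style TIFF tags are read best-effort. Measurement tables go to CSV with
a JSON sidecar documenting units.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field, fields as dc_fields
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import tifffile

logger = logging.getLogger(__name__)

Spacing = tuple[float, float, float]


def _validate_spacing(spacing: Sequence[float]) -> Spacing:
    spacing = tuple(float(s) for s in spacing)
    if len(spacing) != 3:
        raise ValueError(f"spacing must be (dz, dy, dx), got {spacing!r}")
    if not all(np.isfinite(s) and s > 0 for s in spacing):
        raise ValueError(f"spacing components must be positive and finite, got {spacing!r}")
    return spacing  # type: ignore[return-value]


def _validate_grid(data: np.ndarray) -> np.ndarray:
    if data.ndim != 3:
        raise ValueError(f"expected a 3D (z, y, x) grid, got shape {data.shape}")
    if min(data.shape) < 1:
        raise ValueError(f"every axis must have extent >= 1, got shape {data.shape}")
    return data


@dataclass
class IntensityVolume:
    """One imaging channel: a 3D scalar grid plus physical spacing in μm."""

    data: np.ndarray
    spacing: Spacing
    channel: str = ""

    def __post_init__(self) -> None:
        self.data = _validate_grid(np.asarray(self.data))
        self.spacing = _validate_spacing(self.spacing)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    @property
    def voxel_volume(self) -> float:
        """Volume of one voxel in μm³."""
        dz, dy, dx = self.spacing
        return dz * dy * dx


@dataclass
class BinaryMask:
    """3D boolean grid with physical spacing in μm."""

    data: np.ndarray
    spacing: Spacing

    def __post_init__(self) -> None:
        self.data = _validate_grid(np.asarray(self.data).astype(bool))
        self.spacing = _validate_spacing(self.spacing)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    @property
    def voxel_volume(self) -> float:
        dz, dy, dx = self.spacing
        return dz * dy * dx


@dataclass
class LabelVolume:
    """3D instance labelling: non-negative integers, 0 = background.

    ``kind`` records what the instances are (villus, crypt or seed objects).
    """

    data: np.ndarray
    spacing: Spacing
    kind: str = "villus"

    def __post_init__(self) -> None:
        data = np.asarray(self.data)
        if not np.issubdtype(data.dtype, np.integer):
            if not np.array_equal(data, np.round(data)):
                raise ValueError("label grid must be integer-valued")
            data = data.astype(np.int32)
        if data.min() < 0:
            raise ValueError("labels must be non-negative (0 = background)")
        self.data = _validate_grid(data)
        self.spacing = _validate_spacing(self.spacing)
        if self.kind not in ("villus", "crypt", "seed"):
            raise ValueError(f"kind must be villus|crypt|seed, got {self.kind!r}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    @property
    def voxel_volume(self) -> float:
        dz, dy, dx = self.spacing
        return dz * dy * dx

    def label_ids(self) -> np.ndarray:
        """Sorted array of instance ids present (background excluded)."""
        ids = np.unique(self.data)
        return ids[ids > 0]

    def relabel_sequential(self) -> "LabelVolume":
        """Return a copy whose ids form a gap-free 1..N set (order preserved)."""
        ids = self.label_ids()
        lut = np.zeros(int(self.data.max()) + 1, dtype=np.int32)
        lut[ids] = np.arange(1, len(ids) + 1, dtype=np.int32)
        return LabelVolume(lut[self.data], self.spacing, self.kind)


@dataclass
class PointSet:
    """Point detections in physical (z, y, x) μm coordinates (e.g. EdU+ cells)."""

    points: np.ndarray  # (n, 3) float, μm
    label: str = ""

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float)
        if pts.size == 0:
            pts = pts.reshape(0, 3)
        if pts.ndim != 2 or pts.shape[1] != 3:
            raise ValueError(f"points must be (n, 3) (z, y, x) μm, got shape {pts.shape}")
        self.points = pts

    def __len__(self) -> int:
        return len(self.points)

    def check_within(self, shape: Sequence[int], spacing: Sequence[float]) -> np.ndarray:
        """Boolean array: point lies inside the physical bounding box of a volume."""
        spacing = np.asarray(spacing, dtype=float)
        hi = (np.asarray(shape) - 1) * spacing  # last voxel centre
        # allow half a voxel beyond the outermost voxel centres
        return np.all((self.points >= -spacing / 2) & (self.points <= hi + spacing / 2), axis=1)


@dataclass
class VillusMorphometry:
    """Measurements of one villus instance. Units: μm, μm², μm³."""

    sample_id: str
    label_id: int
    length: float = np.nan
    volume: float = np.nan
    surface_area: float = np.nan
    flatness: float = np.nan
    base_contact_area: float = np.nan
    flags: frozenset[str] = field(default_factory=frozenset)

    UNITS = {
        "length": "um",
        "volume": "um^3",
        "surface_area": "um^2",
        "flatness": "dimensionless",
        "base_contact_area": "um^2",
    }


# ---------------------------------------------------------------------------
# TIFF I/O


def _spacing_from_ome(xml: str) -> Spacing | None:
    try:
        meta = tifffile.xml2dict(xml)
    except Exception:  # pragma: no cover - malformed vendor XML
        return None
    try:
        image = meta["OME"]["Image"]
        if isinstance(image, list):
            image = image[0]
        px = image["Pixels"]
        dz = float(px["PhysicalSizeZ"])
        dy = float(px["PhysicalSizeY"])
        dx = float(px["PhysicalSizeX"])
        return (dz, dy, dx)
    except (KeyError, TypeError, ValueError):
        return None


def _spacing_from_imagej(tf: tifffile.TiffFile) -> Spacing | None:
    """Best-effort read of ImageJ-style spacing tags."""
    ij = tf.imagej_metadata
    if not ij or "spacing" not in ij:
        return None
    try:
        dz = float(ij["spacing"])
        page = tf.pages[0]
        xres = page.tags.get("XResolution")
        yres = page.tags.get("YResolution")
        if xres is None or yres is None:
            return None
        dx = xres.value[1] / xres.value[0]
        dy = yres.value[1] / yres.value[0]
        return (dz, dy, dx)
    except (KeyError, TypeError, ZeroDivisionError, IndexError):
        return None


def read_stack(
    path: str | Path,
    spacing_override: Sequence[float] | None = None,
    channel: str = "",
) -> IntensityVolume:
    """Read a TIFF / OME-TIFF stack as an IntensityVolume in (z, y, x) order.

    Spacing resolution: OME metadata when present, else ``spacing_override``;
    when both are present the override wins and a warning is logged. A stack
    with neither is an error — measurements must not silently assume 1 μm.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"stack not found: {path}")
    with tifffile.TiffFile(path) as tf:
        data = tf.asarray()
        meta_spacing = None
        if tf.ome_metadata:
            meta_spacing = _spacing_from_ome(tf.ome_metadata)
        if meta_spacing is None:
            meta_spacing = _spacing_from_imagej(tf)
    if data.ndim == 2:
        data = data[np.newaxis]
    if data.ndim != 3:
        data = np.squeeze(data)
        if data.ndim != 3:
            raise ValueError(f"{path}: expected a single-channel 3D stack, got shape {data.shape}")

    if spacing_override is not None:
        if meta_spacing is not None and tuple(map(float, spacing_override)) != meta_spacing:
            logger.warning(
                "%s: spacing override %s supersedes embedded spacing %s",
                path, tuple(spacing_override), meta_spacing,
            )
        spacing = _validate_spacing(spacing_override)
    elif meta_spacing is not None:
        spacing = _validate_spacing(meta_spacing)
    else:
        raise ValueError(
            f"{path}: no voxel spacing in metadata and no spacing_override given; "
            "pass spacing_override=(dz, dy, dx) in μm"
        )
    return IntensityVolume(data=data, spacing=spacing, channel=channel)


def write_volume(vol: IntensityVolume | BinaryMask | LabelVolume, path: str | Path) -> Path:
    """Write a volume as OME-TIFF with spacing in the metadata.

    Integer and boolean grids round-trip losslessly (bool is stored as uint8
    and restored by the container on re-read).
    """
    path = Path(path)
    if not path.parent.exists():
        raise FileNotFoundError(f"parent directory does not exist: {path.parent}")
    data = vol.data
    if data.dtype == bool:
        data = data.astype(np.uint8)
    dz, dy, dx = vol.spacing
    tifffile.imwrite(
        path,
        data,
        ome=True,
        photometric="minisblack",
        metadata={
            "axes": "ZYX",
            "PhysicalSizeZ": dz,
            "PhysicalSizeY": dy,
            "PhysicalSizeX": dx,
            "PhysicalSizeZUnit": "µm",
            "PhysicalSizeYUnit": "µm",
            "PhysicalSizeXUnit": "µm",
        },
    )
    return path


def read_labels(path: str | Path, spacing_override: Sequence[float] | None = None,
                kind: str = "villus") -> LabelVolume:
    vol = read_stack(path, spacing_override=spacing_override)
    return LabelVolume(vol.data, vol.spacing, kind=kind)


def read_mask(path: str | Path, spacing_override: Sequence[float] | None = None) -> BinaryMask:
    vol = read_stack(path, spacing_override=spacing_override)
    return BinaryMask(vol.data > 0, vol.spacing)


# ---------------------------------------------------------------------------
# Tables and point sets


def _morphometry_to_dict(row: VillusMorphometry) -> dict:
    d = {f.name: getattr(row, f.name) for f in dc_fields(row)}
    d["flags"] = ";".join(sorted(d["flags"]))
    return d


def write_table(rows: Iterable[VillusMorphometry] | Iterable[dict] | pd.DataFrame,
                path: str | Path) -> Path:
    """Write measurement rows as CSV plus a JSON units sidecar.

    Rows are sorted by (sample_id, label_id) so repeated runs are byte
    identical. Mixed schemas are rejected.
    """
    path = Path(path)
    if isinstance(rows, pd.DataFrame):
        df = rows.copy()
    else:
        rows = list(rows)
        dicts: list[dict] = []
        schema: tuple | None = None
        for r in rows:
            d = _morphometry_to_dict(r) if isinstance(r, VillusMorphometry) else dict(r)
            key = tuple(sorted(d))
            if schema is None:
                schema = key
            elif key != schema:
                raise ValueError(f"mixed row schemas: {schema} vs {key}")
            dicts.append(d)
        if dicts:
            df = pd.DataFrame(dicts)
        else:
            df = pd.DataFrame(columns=[f.name for f in dc_fields(VillusMorphometry)])
    sort_cols = [c for c in ("sample_id", "label_id") if c in df.columns]
    if sort_cols:
        df = df.sort_values(sort_cols, kind="mergesort").reset_index(drop=True)
    df.to_csv(path, index=False, lineterminator="\n")
    units = {c: VillusMorphometry.UNITS.get(c, "") for c in df.columns}
    sidecar = path.with_suffix(path.suffix + ".units.json")
    sidecar.write_text(json.dumps(units, indent=2, sort_keys=True) + "\n")
    return path


def read_table(path: str | Path) -> tuple[pd.DataFrame, dict]:
    """Read a CSV written by write_table together with its units sidecar."""
    path = Path(path)
    df = pd.read_csv(path)
    sidecar = path.with_suffix(path.suffix + ".units.json")
    units = json.loads(sidecar.read_text()) if sidecar.exists() else {}
    return df, units


def write_points(points: PointSet, path: str | Path) -> Path:
    path = Path(path)
    payload = {"label": points.label, "points_um_zyx": points.points.tolist()}
    path.write_text(json.dumps(payload, indent=2) + "\n")
    return path


def read_points(path: str | Path) -> PointSet:
    payload = json.loads(Path(path).read_text())
    return PointSet(np.asarray(payload["points_um_zyx"], dtype=float).reshape(-1, 3),
                    label=payload.get("label", ""))
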