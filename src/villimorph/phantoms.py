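"""Synthetic 3D mucosa phantoms with analytically known villus geometry.

Each villus is a capsule — a cylinder of shaft length ``L_c`` capped by a
hemisphere of radius ``r`` — standing on a crypt layer above a mucosal floor.
Flattened villi have an elliptical cross-section with semi-axes
``(a*r, r/a)``, which preserves the cross-section area ``π r²`` so that
flattening is decoupled from volume change. Closed forms for length, volume
and surface area make the phantoms an exact oracle for the measurement
pipeline:

    L = L_c + r
    V = π r² L_c + (2/3) π r³                      (any a: area-preserving)
    S = P(a r, r/a) · L_c + S_cap(a r, r/a, r)     (base disk excluded)

where ``P`` is the ellipse perimeter (complete elliptic integral of the
second kind) and ``S_cap`` the upper-half ellipsoid surface, integrated
numerically to 1e-6 relative tolerance (for a = 1 these reduce to
``2π r L_c + 2π r²``).

Two fluorescence channels are rendered from the geometry: an actin-like
channel (tissue interior plus a bright shell, emulating phalloidin's strong
brush-border/membrane signal) and a nuclei-like channel (speckle inside the
tissue, emulating DAPI), both blurred with an anisotropic Gaussian PSF and
degraded with additive Gaussian noise. All randomness flows from one seed, so
identical specs give bit-identical phantoms.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy import integrate, ndimage, special

from .volumes import BinaryMask, IntensityVolume, LabelVolume, Spacing, _validate_spacing


@dataclass
class VillusParams:
    """Geometry of one capsule villus.

    base_center : (y, x) μm position of the shaft axis at the villus base.
    shaft_length : cylinder length ``L_c`` in μm (tip hemisphere excluded).
    radius : tip/cross-section radius ``r`` in μm.
    anisotropy : cross-section flattening ``a`` ≥ 1; semi-axes ``(a r, r/a)``.
    tilt_polar, tilt_azimuth : axis tilt from vertical (degrees); polar ≤ 30.
    major_axis_azimuth : in-plane orientation of the flat (major) axis, degrees.
    """

    base_center: tuple[float, float]
    shaft_length: float
    radius: float
    anisotropy: float = 1.0
    tilt_polar: float = 0.0
    tilt_azimuth: float = 0.0
    major_axis_azimuth: float = 0.0

    def __post_init__(self) -> None:
        if self.shaft_length < 0 or self.radius <= 0:
            raise ValueError("shaft_length must be >= 0 and radius > 0")
        if self.anisotropy < 1:
            raise ValueError("anisotropy must be >= 1 (1 = circular)")
        if not 0 <= self.tilt_polar <= 30:
            raise ValueError("tilt_polar must be within [0, 30] degrees")


@dataclass
class PhantomSpec:
    """Full description of one synthetic mucosa volume."""

    volume_shape: tuple[int, int, int]
    spacing: Spacing
    villi: list[VillusParams] = field(default_factory=list)
    crypt_layer_depth: float = 30.0
    floor_thickness: float = 10.0
    noise_sd: float = 5.0
    psf_sigma: tuple[float, float, float] = (2.0, 0.8, 0.8)
    rng_seed: int = 0

    def __post_init__(self) -> None:
        self.spacing = _validate_spacing(self.spacing)
        if len(self.volume_shape) != 3 or min(self.volume_shape) < 1:
            raise ValueError(f"volume_shape must be a positive (nz, ny, nx), got {self.volume_shape}")
        if self.crypt_layer_depth < 0 or self.floor_thickness < 0:
            raise ValueError("layer thicknesses must be >= 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")

    @property
    def n_villi(self) -> int:
        return len(self.villi)

    @property
    def base_z(self) -> float:
        """Physical z of the villus base plane (top of the crypt layer)."""
        return self.floor_thickness + self.crypt_layer_depth

    def physical_extent(self) -> tuple[float, float, float]:
        return tuple(n * s for n, s in zip(self.volume_shape, self.spacing))  # type: ignore


@dataclass
class PhantomTruth:
    """Analytic per-villus ground truth implied by a PhantomSpec."""

    label_ids: np.ndarray          # int, 1..n
    length: np.ndarray             # μm, L_c + r
    volume: np.ndarray             # μm³
    surface_area: np.ndarray       # μm², lateral + cap, base excluded
    flatness: np.ndarray           # a (axis-ratio flatness is a²)
    base_contact_area: np.ndarray  # μm², π r² (area-preserving ellipse)

    def as_dict_rows(self, sample_id: str = "phantom") -> list[dict]:
        return [
            {
                "sample_id": sample_id,
                "label_id": int(i),
                "length": float(l),
                "volume": float(v),
                "surface_area": float(s),
                "flatness": float(a),
                "base_contact_area": float(b),
            }
            for i, l, v, s, a, b in zip(
                self.label_ids, self.length, self.volume,
                self.surface_area, self.flatness, self.base_contact_area,
            )
        ]


# ---------------------------------------------------------------------------
# Geometry helpers


def _villus_frame(v: VillusParams) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Orthonormal frame (u, e1, e2) in (z, y, x): axis, major, minor."""
    th = np.deg2rad(v.tilt_polar)
    ph = np.deg2rad(v.tilt_azimuth)
    u = np.array([np.cos(th), np.sin(th) * np.cos(ph), np.sin(th) * np.sin(ph)])
    ps = np.deg2rad(v.major_axis_azimuth)
    e1_flat = np.array([0.0, np.cos(ps), np.sin(ps)])
    # project the requested in-plane major direction onto the plane normal to u
    e1 = e1_flat - np.dot(e1_flat, u) * u
    n1 = np.linalg.norm(e1)
    if n1 < 1e-12:  # axis parallel to requested major direction; pick any normal
        helper = np.array([1.0, 0.0, 0.0])
        e1 = helper - np.dot(helper, u) * u
        n1 = np.linalg.norm(e1)
    e1 /= n1
    e2 = np.cross(u, e1)
    return u, e1, e2


def _base_point(spec: PhantomSpec, v: VillusParams) -> np.ndarray:
    """Physical (z, y, x) of the shaft axis at the base plane.

    A tilted villus is lifted so its flat base disk clears the crypt layer;
    the analytic solid is then never truncated by the floor.
    """
    lift = v.anisotropy * v.radius * np.sin(np.deg2rad(v.tilt_polar))
    return np.array([spec.base_z + lift, v.base_center[0], v.base_center[1]])


def _scaled_capsule_distance(
    pts: np.ndarray, p0: np.ndarray, v: VillusParams
) -> np.ndarray:
    """Distance (μm) to the capsule axis segment in flattening-scaled space.

    In coordinates (t, s1/a, s2*a) the elliptical capsule becomes a circular
    capsule of radius r; inside-test is distance <= r with t clamped to
    [0, L_c] and the basal half-space (t < 0) excluded by returning +inf.
    """
    u, e1, e2 = _villus_frame(v)
    w = pts - p0
    t = w @ u
    s1 = (w @ e1) / v.anisotropy
    s2 = (w @ e2) * v.anisotropy
    tc = np.clip(t, 0.0, v.shaft_length)
    d = np.sqrt((t - tc) ** 2 + s1**2 + s2**2)
    return np.where(t < 0, np.inf, d)


def _pairwise_clearance(spec: PhantomSpec, i: int, j: int, n_samples: int = 64) -> float:
    """Conservative surface clearance between villi i and j (μm).

    Uses the distance between axis segments minus the two largest semi-axes;
    exact for circular cross-sections, conservative (under-estimates) for
    elliptical ones.
    """
    vi, vj = spec.villi[i], spec.villi[j]
    pi = _base_point(spec, vi)
    pj = _base_point(spec, vj)
    ui = _villus_frame(vi)[0]
    uj = _villus_frame(vj)[0]
    ti = np.linspace(0, vi.shaft_length, n_samples)[:, None]
    tj = np.linspace(0, vj.shaft_length, n_samples)[:, None]
    ai = pi + ti * ui
    aj = pj + tj * uj
    dmin = np.min(np.linalg.norm(ai[:, None, :] - aj[None, :, :], axis=-1))
    return float(dmin - vi.anisotropy * vi.radius - vj.anisotropy * vj.radius)


def validate_spec(spec: PhantomSpec) -> PhantomSpec:
    """Check the phantom invariants; return the spec unchanged if they hold.

    Raises ValueError naming the offending villus ids when villi overlap
    (surface clearance <= 0), leave the volume bounding box, or the spacing
    is invalid (already enforced by the dataclass).
    """
    ez, ey, ex = spec.physical_extent()
    out_of_bounds: list[int] = []
    for idx, v in enumerate(spec.villi, start=1):
        p0 = _base_point(spec, v)
        u, e1, e2 = _villus_frame(v)
        shaft_top = p0 + v.shaft_length * u
        A, B, r = v.anisotropy * v.radius, v.radius / v.anisotropy, v.radius
        # exact per-axis half-extents: shaft cross-section (ellipse in the
        # e1/e2 plane) and tip cap (ellipsoid with extra r along u)
        shaft_ext = np.sqrt((A * e1) ** 2 + (B * e2) ** 2)
        cap_ext = np.sqrt((r * u) ** 2 + (A * e1) ** 2 + (B * e2) ** 2)
        lo = np.minimum(p0 - shaft_ext, shaft_top - cap_ext)
        hi = np.maximum(p0 + shaft_ext, shaft_top + cap_ext)
        if not (lo[1] >= -1e-9 and hi[1] <= ey + 1e-9
                and lo[2] >= -1e-9 and hi[2] <= ex + 1e-9
                and hi[0] <= ez + 1e-9):
            out_of_bounds.append(idx)
    if out_of_bounds:
        raise ValueError(f"villi out of volume bounds: ids {sorted(set(out_of_bounds))}")

    overlapping: set[int] = set()
    for i in range(spec.n_villi):
        for j in range(i + 1, spec.n_villi):
            if _pairwise_clearance(spec, i, j) <= 0:
                overlapping.update((i + 1, j + 1))
    if overlapping:
        raise ValueError(f"overlapping villi: ids {sorted(overlapping)}")
    return spec


# ---------------------------------------------------------------------------
# Analytic morphometry


def ellipse_perimeter(semi_major: float, semi_minor: float) -> float:
    """Perimeter of an ellipse via the complete elliptic integral E(m)."""
    a, b = max(semi_major, semi_minor), min(semi_major, semi_minor)
    if a == 0:
        return 0.0
    m = 1.0 - (b / a) ** 2
    return 4.0 * a * float(special.ellipe(m))


def half_ellipsoid_area(A: float, B: float, C: float, rel_tol: float = 1e-9) -> float:
    """Lateral surface of the upper half-ellipsoid with semi-axes (A, B, C).

    C is the polar (vertical) semi-axis; the equatorial base disk is not
    included. Numerically integrated; converged well below 1e-6 relative.
    """

    def integrand(theta: float, phi: float) -> float:
        st, ct = np.sin(theta), np.cos(theta)
        cp, sp = np.cos(phi), np.sin(phi)
        g = np.sqrt((B * C * cp * st) ** 2 + (A * C * sp * st) ** 2 + (A * B * ct) ** 2)
        return st * g

    val, _ = integrate.dblquad(
        integrand, 0.0, 2.0 * np.pi, 0.0, np.pi / 2.0,
        epsabs=0.0, epsrel=rel_tol,
    )
    return float(val)


def analytic_morphometry(spec: PhantomSpec) -> PhantomTruth:
    """Closed-form per-villus length, volume and surface area.

    Volume and length are exact for every anisotropy; the surface combines the
    exact elliptic-cylinder lateral term with a numerically integrated
    half-ellipsoid cap (relative tolerance 1e-6).
    """
    n = spec.n_villi
    ids = np.arange(1, n + 1, dtype=int)
    length = np.empty(n)
    volume = np.empty(n)
    surface = np.empty(n)
    flat = np.empty(n)
    base_area = np.empty(n)
    for k, v in enumerate(spec.villi):
        r, Lc, a = v.radius, v.shaft_length, v.anisotropy
        length[k] = Lc + r
        volume[k] = np.pi * r**2 * Lc + (2.0 / 3.0) * np.pi * r**3
        lateral = ellipse_perimeter(a * r, r / a) * Lc
        cap = half_ellipsoid_area(a * r, r / a, r)
        surface[k] = lateral + cap
        flat[k] = a
        base_area[k] = np.pi * r**2
    return PhantomTruth(ids, length, volume, surface, flat, base_area)


# ---------------------------------------------------------------------------
# Rasterization and rendering


def _physical_grids(shape, spacing):
    dz, dy, dx = spacing
    z = np.arange(shape[0]) * dz
    y = np.arange(shape[1]) * dy
    x = np.arange(shape[2]) * dx
    return np.meshgrid(z, y, x, indexing="ij")


def rasterize_labels(spec: PhantomSpec) -> LabelVolume:
    """Voxelize each villus (inside-test at voxel centres) into a label grid.

    Villi are non-overlapping by validation, so paint order is irrelevant;
    each is rasterized only inside its bounding box for speed.
    """
    dz, dy, dx = spec.spacing
    labels = np.zeros(spec.volume_shape, dtype=np.int32)
    for idx, v in enumerate(spec.villi, start=1):
        p0 = _base_point(spec, v)
        u = _villus_frame(v)[0]
        tip = p0 + (v.shaft_length + v.radius) * u
        rmax = v.anisotropy * v.radius
        lo = np.minimum(p0, tip) - rmax
        hi = np.maximum(p0, tip) + rmax
        k0 = max(int(np.floor(lo[0] / dz)), 0)
        k1 = min(int(np.ceil(hi[0] / dz)) + 1, spec.volume_shape[0])
        j0 = max(int(np.floor(lo[1] / dy)), 0)
        j1 = min(int(np.ceil(hi[1] / dy)) + 1, spec.volume_shape[1])
        i0 = max(int(np.floor(lo[2] / dx)), 0)
        i1 = min(int(np.ceil(hi[2] / dx)) + 1, spec.volume_shape[2])
        if k0 >= k1 or j0 >= j1 or i0 >= i1:
            continue
        zz, yy, xx = np.meshgrid(
            np.arange(k0, k1) * dz, np.arange(j0, j1) * dy, np.arange(i0, i1) * dx,
            indexing="ij",
        )
        pts = np.stack([zz.ravel(), yy.ravel(), xx.ravel()], axis=1)
        inside = _scaled_capsule_distance(pts, p0, v) <= v.radius
        sub = labels[k0:k1, j0:j1, i0:i1]
        sub[inside.reshape(sub.shape)] = idx
    return LabelVolume(labels, spec.spacing, kind="villus")


def _layer_masks(spec: PhantomSpec) -> tuple[np.ndarray, np.ndarray]:
    """(floor, crypt-layer) boolean slabs from physical z thresholds."""
    dz = spec.spacing[0]
    z = np.arange(spec.volume_shape[0]) * dz
    floor = z < spec.floor_thickness
    crypt = (z >= spec.floor_thickness) & (z < spec.base_z)
    shape = spec.volume_shape
    floor3 = np.broadcast_to(floor[:, None, None], shape).copy()
    crypt3 = np.broadcast_to(crypt[:, None, None], shape).copy()
    return floor3, crypt3


def generate_phantom(
    spec: PhantomSpec,
) -> tuple[IntensityVolume, IntensityVolume, LabelVolume, BinaryMask, PhantomTruth]:
    """Render a validated phantom.

    Returns ``(nuclei, actin, truth_labels, crypt_mask, truth)``. The crypt
    mask covers the whole sub-base slab (floor plus crypt layer) so removing
    it leaves exactly the villi. Identical specs (including rng_seed) give
    bit-identical outputs.
    """
    validate_spec(spec)
    rng = np.random.default_rng(spec.rng_seed)
    labels = rasterize_labels(spec)
    floor3, crypt3 = _layer_masks(spec)
    tissue = (labels.data > 0) | floor3 | crypt3

    spacing = np.asarray(spec.spacing)
    # shell = tissue voxels within ~1.5 μm of the tissue boundary
    interior = ndimage.distance_transform_edt(tissue, sampling=spacing) > 1.5
    shell = tissue & ~interior

    # phalloidin-like contrast: cytoplasmic/cortical actin throughout the
    # tissue with enhanced apical brush-border signal in a surface shell
    actin = np.zeros(spec.volume_shape, dtype=np.float64)
    actin[tissue] = 150.0
    actin[shell] = 200.0

    nuclei = np.zeros(spec.volume_shape, dtype=np.float64)
    n_tissue = int(tissue.sum())
    if n_tissue:
        # nuclear speckle: ~8% of tissue voxels carry a bright kernel
        speckle = rng.random(n_tissue) < 0.08
        vals = np.zeros(n_tissue)
        vals[speckle] = 180.0
        nuclei[tissue] = vals

    sigma_vox = np.asarray(spec.psf_sigma) / spacing
    actin = ndimage.gaussian_filter(actin, sigma=sigma_vox)
    nuclei = ndimage.gaussian_filter(nuclei, sigma=sigma_vox)
    if spec.noise_sd > 0:
        actin = actin + rng.normal(0.0, spec.noise_sd, size=actin.shape)
        nuclei = nuclei + rng.normal(0.0, spec.noise_sd, size=nuclei.shape)

    truth = analytic_morphometry(spec)
    return (
        IntensityVolume(nuclei, spec.spacing, channel="nuclei"),
        IntensityVolume(actin, spec.spacing, channel="actin"),
        labels,
        BinaryMask(floor3 | crypt3, spec.spacing),
        truth,
    )


def paired_cohort_specs(
    n_phantoms: int,
    villi_per_phantom: int,
    rng: np.random.Generator | int | None = None,
    spacing: Sequence[float] = (1.0, 0.5, 0.5),
    radius_range: tuple[float, float] = (5.0, 7.0),
    length_range: tuple[float, float] = (35.0, 50.0),
    length_scale: float = 1.5,
    flattening: float = 2.0,
    clearance: float = 2.0,
    crypt_layer_depth: float = 8.5,
    floor_thickness: float = 4.0,
    noise_sd: float = 5.0,
    psf_sigma: tuple[float, float, float] = (1.0, 0.5, 0.5),
) -> tuple[list[PhantomSpec], list[PhantomSpec]]:
    """Build a matched two-condition synthetic cohort.

    The first (control) cohort has circular villi with lengths drawn from
    ``length_range``. The second (expanded) cohort reuses the *same* sampled
    geometry with every villus length multiplied by ``length_scale`` and the
    cross-section flattened by ``flattening`` — emulating villus expansion
    with a flattened geometry while keeping the two cohorts paired, so the
    expected group length ratio is exactly ``length_scale``.

    Villi are placed on a regular grid with pitch sized for the flattened
    footprint, so both members of each pair validate by construction.
    """
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    ctrl: list[PhantomSpec] = []
    expanded: list[PhantomSpec] = []
    side = int(np.ceil(np.sqrt(villi_per_phantom)))
    r_hi = radius_range[1]
    pitch = 2 * flattening * r_hi + clearance + 2.0
    lateral = side * pitch
    base = floor_thickness + crypt_layer_depth
    l_hi = length_range[1] * length_scale
    nz = int(np.ceil((base + l_hi + 4.0) / spacing[0]))
    ny = int(np.ceil(lateral / spacing[1]))
    nx = int(np.ceil(lateral / spacing[2]))
    for p in range(n_phantoms):
        villi_c: list[VillusParams] = []
        villi_e: list[VillusParams] = []
        for k in range(villi_per_phantom):
            gy, gx = divmod(k, side)
            center = ((gy + 0.5) * pitch, (gx + 0.5) * pitch)
            r = rng.uniform(*radius_range)
            L = rng.uniform(*length_range)
            villi_c.append(VillusParams(center, max(L - r, 0.0), r))
            villi_e.append(VillusParams(center, max(length_scale * L - r, 0.0), r,
                                        anisotropy=flattening))
        seed_c = int(rng.integers(0, 2**31 - 1))
        seed_e = int(rng.integers(0, 2**31 - 1))
        common = dict(
            volume_shape=(nz, ny, nx), spacing=tuple(spacing),
            crypt_layer_depth=crypt_layer_depth, floor_thickness=floor_thickness,
            noise_sd=noise_sd, psf_sigma=tuple(psf_sigma),
        )
        ctrl.append(validate_spec(PhantomSpec(villi=villi_c, rng_seed=seed_c, **common)))
        expanded.append(validate_spec(PhantomSpec(villi=villi_e, rng_seed=seed_e, **common)))
    return ctrl, expanded


# ---------------------------------------------------------------------------
# Random spec construction


def random_phantom_spec(
    n_villi: int,
    rng: np.random.Generator | int | None = None,
    volume_shape: tuple[int, int, int] | None = None,
    spacing: Sequence[float] = (2.15, 0.62, 0.62),
    radius_range: tuple[float, float] = (20.0, 40.0),
    length_range: tuple[float, float] = (200.0, 600.0),
    anisotropy_range: tuple[float, float] = (1.0, 1.0),
    tilt_max: float = 0.0,
    clearance: float = 5.0,
    max_tries: int = 2000,
    **spec_kwargs,
) -> PhantomSpec:
    """Rejection-sample a valid phantom with ``n_villi`` non-overlapping villi.

    Defaults target the tissue scale of murine small-intestinal villi
    (radii tens of μm, lengths hundreds of μm) at a typical anisotropic
    confocal spacing. Tests and the acceptance pipeline pass smaller explicit
    geometry.
    """
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    r_hi = radius_range[1] * max(anisotropy_range[1], 1.0)
    l_hi = length_range[1]
    floor = spec_kwargs.get("floor_thickness", 10.0)
    crypt = spec_kwargs.get("crypt_layer_depth", 30.0)
    if volume_shape is None:
        # square lateral packing with margin, z to fit the tallest villus
        side = int(np.ceil(np.sqrt(n_villi))) if n_villi else 1
        pitch = 2 * r_hi + clearance + 2.0
        lateral = side * pitch + 2 * r_hi
        nz = int(np.ceil((floor + crypt + l_hi + r_hi + 4.0) / spacing[0]))
        ny = int(np.ceil(lateral / spacing[1]))
        nx = int(np.ceil(lateral / spacing[2]))
        volume_shape = (nz, ny, nx)

    spec = PhantomSpec(
        volume_shape=volume_shape, spacing=tuple(spacing),  # type: ignore[arg-type]
        villi=[], rng_seed=int(rng.integers(0, 2**31 - 1)), **spec_kwargs,
    )
    ez, ey, ex = spec.physical_extent()
    villi: list[VillusParams] = []
    tries = 0
    while len(villi) < n_villi:
        tries += 1
        if tries > max_tries:
            raise RuntimeError(
                f"could not place {n_villi} villi with clearance {clearance} μm "
                f"in a {ey:.0f}x{ex:.0f} μm field after {max_tries} tries"
            )
        r = rng.uniform(*radius_range)
        a = rng.uniform(*anisotropy_range)
        Lc = max(rng.uniform(*length_range) - r, 0.0)
        margin = a * r + 1.0
        cand = VillusParams(
            base_center=(rng.uniform(margin, ey - margin), rng.uniform(margin, ex - margin)),
            shaft_length=Lc,
            radius=r,
            anisotropy=a,
            tilt_polar=rng.uniform(0.0, tilt_max),
            tilt_azimuth=rng.uniform(0.0, 360.0),
            major_axis_azimuth=rng.uniform(0.0, 180.0),
        )
        trial = replace(spec, villi=villi + [cand])
        ok = True
        i = len(villi)
        for j in range(i):
            if _pairwise_clearance(trial, i, j) <= clearance:
                ok = False
                break
        if ok:
            try:
                validate_spec(replace(spec, villi=[cand]))
            except ValueError:
                ok = False
        if ok:
            villi.append(cand)
    spec.villi = villi
    return validate_spec(spec)
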