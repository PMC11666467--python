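# Methods

## Problem and data model

Whole-mount confocal stacks of small-intestinal mucosa show a floor of
tissue carrying a crypt layer and, above it, finger-like villi. The voxel
grid is strongly anisotropic: the z-step of such acquisitions (~2.15 μm) is
several times the lateral pixel size, so every geometric operation in this
package works in physical micrometres, never in raw voxel counts. Axis order
is `(z, y, x)` with the slice index leading; voxel `(k, j, i)` has physical
centre `(k·dz, j·dy, i·dx)`; spacing is mandatory on every container because
a silent 1 μm default would corrupt all downstream measurements.

## Crypt masking and the base surface

Crypts are annotated manually on a few slices. Interpolation to 3D is
shape-based: each annotated slice is converted to a signed 2D Euclidean
distance field (negative inside), unannotated slices between two annotated
ones take the z-linear interpolation of the bracketing fields, slices
outside the annotated range copy the nearest field, and the mask is the
non-positive set. This realises "interpolate between sparse annotations"
deterministically and handles growing/shrinking regions without topology
surgery; linearly interpolated signed distance fields of concentric disks
interpolate the radius linearly, which the tests exploit. Polygons are
rasterised at pixel centres (even-odd rule).

Removing the crypt mask from the foreground leaves the villi; the remaining
voxels 26-adjacent to the crypt mask form the **base surface** — the source
set of every length measurement. With no crypt mask (cropped stacks,
floor-less phantoms) the z = 0 face is used and the fallback is logged and
flagged per instance.

## Segmentation

Seeding iterates a binary operation with band-pass filtering: at iteration k
the mask is eroded by a ball of physical radius `k·erosion_step` (realised
as a threshold on the anisotropic EDT, so "ball" means a true μm ball), the
Laplacian of Gaussian of the distance transform is evaluated at the k-th
scale of a decreasing schedule, and regional maxima of the sign-flipped
response *inside* the eroded mask are grouped by the 26-connected eroded
component they lie in — one seed per component. The distance transform of a
finger-like object has its strongest blob response inside the rounded tip,
so a villus contributes one seed even when its shaft response forms a ridge
with several local maxima; fused villi separate as soon as erosion cuts
their neck. Iteration stops when the seed count is unchanged over two
consecutive iterations or after `max_iterations`. Seeds smaller than
`min_seed_volume` μm³ are discarded. The LoG is applied to the distance
transform rather than raw intensity (seeds must reflect object shape, not
staining texture); `seed_field="intensity"` is available for sensitivity
analysis.

Two practical constraints on the parameters: `erosion_step` must stay below
the narrowest expected villus half-width (for flattened cross-sections that
is `r/a`), and the LoG scales should bracket the expected radius range. The
benchmark configuration for the r ≈ 5–7 μm phantoms uses schedule
[6, 4, 2.5] μm, erosion step 1 μm, downsampling (1, 2, 2).

Regrowth is marker-controlled flooding by **within-mask geodesic distance**:
every mask voxel joins the seed with the smallest shortest-path distance on
the 26-connected voxel graph with physical edge lengths, ties broken by
smaller label id then smaller linear index, labels renumbered 1..N by
descending volume. Geodesic flooding (rather than flooding ranked by the
negated EDT elevation) was chosen because it has an exact independent oracle
— per-seed Dijkstra — against which the implementation is verified voxel for
voxel, and because on crypt-free mucosa the villi are near-separate objects
where both variants coincide except on the rare fused necks. The production
engine is `scipy.sparse.csgraph.dijkstra` over an explicitly built sparse
voxel graph with one zero-weight virtual node per marker; the reference
implementation is an independent pure-Python heapq Dijkstra kept only for
cross-checks.

## Morphometry

* **Length** — the maximum of the geodesic distance map started at the
  instance's base voxels. A geodesic (within-object) map was preferred over
  an unconstrained Euclidean map because tilted or curved villi would
  otherwise be measured through the lumen. No half-voxel end corrections are
  applied; the bias is far below the validation tolerances and exact oracle
  agreement is worth more than a sub-voxel correction. 26-connected path
  length overestimates true Euclidean length by at most ~3.5% for
  arbitrarily oriented straight runs (the chamfer bound); upright villi are
  measured essentially exactly.
* **Volume** — voxel count × `dz·dy·dx`.
* **Surface area** — default: Crofton 13-direction estimator. Transitions of
  the binary instance are counted along the 13 half-neighbourhood grid
  directions; direction k with physical period `d_k` and weight `w_k`
  contributes `2·w_k·(v/d_k)·N_k` (`v` = voxel volume, `N_k` = transition
  count), which is the discrete Cauchy projection formula. The weights are
  **calibrated**: exactness requires `Σ_k w_k |n·u_k| = 1/2` for every
  surface normal `n`, and on anisotropic grids the classical
  spherical-partition weights leave an orientation-dependent bias of several
  percent (−5% on a vertical capsule at (1, 0.5, 0.5) μm); solving the
  condition by non-negative least squares over a dense deterministic normal
  sampling reduces that to ~1%. Weights depend only on the direction set, so
  uniform spacing scaling leaves them bit-identical and the `s²` surface
  scaling law holds exactly. The alternative method triangulates the
  half-level set by marching cubes and relaxes the staircase with Taubin's
  non-shrinking filter (λ = 0.5, ν = 0.6, 20 iterations) before measuring:
  raw binary isosurfaces overestimate smooth surfaces by up to ~10%, while
  flat faces are fixed points of the filter, so boxes remain boxes. Both
  estimators measure the full instance boundary including the flat base cut;
  for comparison with base-free analytic surfaces the measured base contact
  area is subtracted.
* **Flatness** — instances are sliced by slabs (2·max spacing thick)
  perpendicular to the principal axis of their voxel-position covariance;
  per slab the 2D covariance eigenvalues give an axis ratio
  `sqrt(λ_major/λ_minor)` and the median over slabs is reported together
  with the volume-weighted mean major-axis direction. For an elliptical
  cross-section with semi-axes `(a·r, r/a)` the expected ratio is `a²`.
  Instances under 10 voxels or with degenerate slabs are flagged, not
  raised.
* **Crypt depth / villus-crypt ratio** — depth is the maximum geodesic
  distance from the crypt's opening voxels; the ratio is a plain quotient,
  flagged undefined for non-positive depth.
* **EdU migration distance** — points in physical coordinates snap to their
  nearest epithelium voxel within one voxel diagonal (otherwise flagged
  off-tissue) and the distance is the maximum geodesic distance from the
  base over the snapped points, 0-with-flag when none remain.
* **Organoid area** — 8-connected 2D components × pixel area;
  border-touching components are flagged.

Quality flags never abort a batch: degenerate instances yield flagged rows
so cohort tables keep one row per label.

## Synthetic phantoms

Villi are capsules — cylinder of shaft length `L_c` plus hemispherical tip
of radius `r` — standing on a crypt slab over a floor slab, optionally
tilted up to 30° and flattened to an elliptical cross-section with semi-axes
`(a·r, r/a)`. Area-preserving flattening decouples the shape claim from
volume change. Closed forms: `L = L_c + r`, `V = π r² L_c + (2/3) π r³`
(any `a`), `S = P(a·r, r/a)·L_c + S_cap` with the ellipse perimeter from the
complete elliptic integral of the second kind and the half-ellipsoid cap
integrated numerically (relative tolerance 1e-6; verified against an
independent parametrisation and a 0.15 μm marching-cubes mesh to 3e-5).
Tilted villi are lifted so their flat base disk clears the crypt layer,
keeping the analytic solid untruncated (tilt defaults to 0 in the validation
phantoms).

Voxelization is an inside-test at voxel centres with no partial-volume
weighting. One consequence worth knowing: when the base plane coincides
exactly with a voxel-centre lattice plane, the ≤-inclusive test adds half a
slice of volume to every villus; the validation phantoms therefore place the
base plane between voxel centres (e.g. crypt depth 8.5 μm at dz = 1 μm).

Rendering is deliberately simple — the pipeline's operators, not
photorealism, are under test. The actin-like channel paints the tissue
interior at 150 and a ~1.5 μm surface shell at 200 (phalloidin stains
cortical actin throughout the epithelium with enhanced apical brush-border
signal; the moderate shell:interior contrast keeps the histogram bimodal
between background and tissue so that a global threshold lands near the
half-amplitude edge crossing). The nuclei-like channel is random speckle
(8% of tissue voxels at 180). Both are blurred with an anisotropic Gaussian
PSF and degraded with additive Gaussian noise; all randomness flows from a
single seed, so identical specs render bit-identically. The phantoms do
*not* emulate depth-dependent attenuation, spherical aberration, autofluorescent
lamina propria, touching/fused villi beyond simple necks, or Poisson photon
noise — passing tests therefore demonstrate correctness of the geometry
pipeline under a clean imaging model, not robustness to every real-world
artefact.

## Cohort statistics

Summaries (n, mean, s.e.m. = sd/√n, median, IQR) are always emitted at both
the villus level and the mouse level (per-mouse means first), because
villus-level n overstates the independent sample size when several villi
come from one mouse; the package surfaces both rather than choosing.
Two-group comparisons default to Welch's two-tailed t-test — the safer
default when the variance assumption is unstated — with the classical pooled
test available via `equal_var=True`. Multi-group designs use one-way ANOVA
with Tukey's HSD over all pairs; no correction is applied across metrics.

## Validation design and problem sizes

Realistic murine tissue geometry (radii 20–40 μm, lengths 200–600 μm) is the
default of the random-spec helper, but the validation suite runs scaled-down
capsules (r ≈ 5–7 μm, L ≈ 35–50 μm, ~2 M voxel volumes at (1, 0.5, 0.5) μm)
that preserve a realistic length:radius aspect while keeping the whole suite
a few minutes on one CPU; measurement errors depend on voxels per radius,
not absolute size, so the scaled phantoms are the stricter test. The
benchmark battery (`villimorph.benchmarks`, driven by
`scripts/acceptance.py`): 20-villus instance recovery under 20 rendering
seeds; median measurement error against analytic truth (length and volume
within 3%, both surface estimators within 5%; flatness of a = 2 villi within
15% of 4); voxel-exact agreement of marker regrowth with a brute-force
nearest-seed Dijkstra partition and 1e-9 agreement of geodesic fields on 50
random masks; exact s/s²/s³ scaling under spacing scaling; a matched
nulliparous-vs-lactation cohort (5 phantoms per arm, lengths ×1.5, a = 2)
recovering the length ratio within 5% with Tukey p < 0.001 and significantly
higher flatness; ANOVA type-I error 5% ± 2% over 1000 null simulations; and
byte-identical pipeline reruns.

## Known limitations

* The count-stability stopping rule of the seeding iteration can stop before
  fused villi separate (or after thin ones erode away) if `erosion_step` is
  mismatched to the villus width; the run-log records per-iteration seed
  counts so such runs are auditable.
* Global Otsu binarization of the rendered channel biases the recovered
  foreground by a fraction of the PSF width; end-to-end volumes carry a
  percent-level offset that the truth-label measurements do not.
* Crofton weight calibration assumes the surface normal distribution of
  generic smooth objects; long axis-aligned polyhedra are measured better by
  the mesh method.
* Branched or fused-tip villi, out-of-core volumes and proprietary
  microscope formats are out of scope.
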