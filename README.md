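# villimorph

3D morphometry of intestinal villi from fluorescence confocal stacks:
instance segmentation of the finger-like villi and per-villus physical
measurements — length, volume, surface area, cross-sectional flatness — plus
the auxiliary readouts used in gut-expansion studies (crypt depth and
villus/crypt ratio, EdU-based epithelial migration distance, organoid
cross-section area) and two-level cohort statistics.

The package is written for tissue biologists quantifying small-intestinal
remodelling (e.g. the villous expansion of pregnancy/lactation) from
whole-mount DAPI/phalloidin stacks with strongly anisotropic voxels
(a z-step of ~2.15 μm against sub-micron pixels is typical).

## Method

Given an actin (phalloidin) channel and sparse manual crypt annotations:

1. **Crypt masking** — the crypt region annotated on a few 2D slices is
   interpolated to 3D by linear interpolation of per-slice signed distance
   fields; the crypt mask is removed so only villi remain, and the remaining
   voxels touching the crypt mask define the villus **base surface**.
2. **Seeding** — the crypt-free mask is downsampled and eroded iteratively
   (in μm, via the anisotropic Euclidean distance transform); regional maxima
   of the sign-flipped Laplacian-of-Gaussian of the distance transform,
   grouped by eroded component, become one seed per villus.
3. **Regrowth** — seeds are regrown to the full mask by marker-controlled
   flooding along within-mask geodesic distance, with a deterministic
   tie-break; labels are upsampled back to full resolution.
4. **Morphometry** — per villus: length = max of the geodesic distance map
   started at the base, `L = max_x d_g(base, x)`; volume = voxel count ×
   `dz·dy·dx`; surface area by a 13-direction Crofton estimator with
   orientation-calibrated weights (triangulated-mesh area as cross-check);
   flatness = median per-slice axis ratio `sqrt(λ_major/λ_minor)` of
   cross-section covariances perpendicular to the principal axis.
5. **Cohort reporting** — per-group mean ± s.e.m. at both villus and mouse
   level, Welch t-tests or one-way ANOVA with Tukey's HSD.

Because raw stacks of this kind are rarely shared, the package includes a
**synthetic phantom generator**: villi are capsules (cylinder + hemispherical
tip, optionally flattened to an area-preserving elliptical cross-section)
with closed-form length `L = L_c + r`, volume `V = π r² L_c + (2/3) π r³`
and surface `S = P(ar, r/a)·L_c + S_cap` — an analytic oracle for every
measurement the pipeline makes.

## Worked example

```python
import numpy as np
from villimorph import (random_phantom_spec, generate_phantom,
                        SeedingParams, segment_villi, measure_villi)

spec = random_phantom_spec(
    5, rng=np.random.default_rng(0), spacing=(1.0, 0.5, 0.5),
    radius_range=(5, 7), length_range=(35, 50), clearance=2.0,
    crypt_layer_depth=8.5, floor_thickness=4.0, noise_sd=5.0,
    psf_sigma=(1.0, 0.5, 0.5))
nuclei, actin, truth_labels, crypt_mask, truth = generate_phantom(spec)

params = SeedingParams(downsample_factors=(1, 2, 2),
                       sigma_schedule=[6.0, 4.0, 2.5],
                       erosion_step=1.0, max_iterations=6,
                       min_seed_volume=1.0)
labels, base = segment_villi(actin, crypt_mask, params)
for row in measure_villi(labels, base, sample_id="demo"):
    print(f"villus {row.label_id}: L={row.length:6.1f} um  "
          f"V={row.volume:8.0f} um^3  S={row.surface_area:7.0f} um^2  "
          f"flatness={row.flatness:4.2f}")
print("analytic lengths:", np.round(sorted(truth.length)[::-1], 1))
```

Output:

```
villus 1: L=  49.0 um  V=    5100 um^3  S=   1955 um^2  flatness=1.03
villus 2: L=  39.0 um  V=    5036 um^3  S=   1820 um^2  flatness=1.01
villus 3: L=  34.0 um  V=    4934 um^3  S=   1718 um^2  flatness=1.02
villus 4: L=  40.0 um  V=    4644 um^3  S=   1733 um^2  flatness=1.01
villus 5: L=  34.0 um  V=    3304 um^3  S=   1323 um^2  flatness=1.01
analytic lengths: [49.7 41.3 39.7 35.2 35. ]
```

All five villi are recovered (labels are ordered by descending volume, not
by analytic id). Measured lengths track the analytic values to within a few
percent; the residual offsets come from thresholding the rendered,
PSF-blurred channel, not from the measurement operators. The reported
surface includes each instance's flat base cut; subtract
`base_contact_area` to compare with base-free analytic surfaces.

The same steps are available from the shell:

```bash
villimorph phantom --config spec.yaml --out phantom/
villimorph segment --stack actin.ome.tif --crypts annos.json \
                   --params params.yaml --out labels.ome.tif
villimorph measure --labels labels.ome.tif --base labels.base.json \
                   --surface both --out morphometry.csv
villimorph run     --config pipeline.yaml --out results/
```

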