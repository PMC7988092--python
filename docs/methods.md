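# Methods

## The margin model

Ablation margins are clinically defined as the rim of necrosis between the
tumor boundary and the ablation boundary.  `qamargin` quantifies it per
tumor surface voxel as a signed exact Euclidean distance to the ablation
boundary, computed on the voxel lattice:

1. **Input contract.**  Tumor, ablation and (optionally) liver masks must
   be binary and share grid dimensions and voxel spacing; registration and
   resampling are prerequisites performed upstream.  Masks stored as float
   0.0/1.0 are accepted and thresholded at > 0.5; any additional label
   values are rejected.  Identical shape with differing affines produces a
   warning, not an error — computation uses 0-based voxel indices and the
   spacing vector only, and distances are between voxel centres.
2. **Crop (optional).**  All volumes are cropped to the union bounding box
   of the foreground plus ≥ 2 voxels of padding.  Because erosion only
   inspects face neighbours and the sampled distance values only depend on
   voxels inside the padded box, the reported results are bit-identical
   with and without cropping (asserted in the test suite).
3. **Surface extraction.**  The contour of a mask is the mask minus its
   6-connected (face-connectivity) erosion, with everything outside the
   grid treated as background.  This keeps the contour one voxel thin
   while retaining corner voxels along large edges.
4. **Signed distance map** of the ablation, exact (no chamfer
   approximation) and spacing-aware, so anisotropic grids need no
   resampling.  Background voxels are negated: a tumor surface voxel
   outside the ablation reads as a negative margin.
5. **Subcapsular exclusion** (optional): tumor surface voxels strictly
   closer than a threshold (default 5 mm, the accepted minimal-margin
   definition) to the liver contour are removed from the distribution.
6. **Margin extraction.**  The signed map is sampled at the included tumor
   contour voxels.

## Two zero-set conventions

The distance transform needs a zero set, and two natural choices exist on
a voxel lattice.  Both are implemented; results state which was used.

* `zero_set="surface"` (default): distances are measured to the extracted
  ablation **contour voxels**.  Contour voxels map to exactly 0, so a
  tumor identical to its ablation yields margin 0 everywhere, and a tumor
  surface voxel lying on the ablation contour contributes +0 (it falls in
  the 0–5 mm class; only background voxels are negated).
* `zero_set="interface"`: the classical signed EDT of the binary mask,
  `edt(mask) − edt(~mask)` — each voxel's distance to the nearest voxel of
  the **opposite phase**.  The implied boundary lies between voxel
  centres, so magnitudes are at least one voxel step; identical masks
  yield +1-voxel margins.  Interior distances are larger by roughly half a
  voxel diagonal than under `surface`.

The conventions agree in sign everywhere and differ only in how the
discrete boundary is placed.  The published reference values for the
artificial sphere cases (below) follow the `interface` convention — under
`surface` the T2.2 fractions are provably unreachable, because with a
fully covering 15 mm ablation no contour-to-contour distance from a 10 mm
tumor's surface can reach 5 mm — so the built-in phantom verification and
the acceptance script use `interface`, while the library default remains
`surface`, whose zero-on-contour behaviour is the natural contract for
surface-to-surface distances.

## Reporting

Per distribution the package reports `n_included` / `n_excluded`, min,
25th/50th/75th percentile and max (linear interpolation between closest
ranks by default; a closest-observation method is available), traffic-light
class fractions (orange x < 0, yellow 0 ≤ x < 5, green x ≥ 5 mm;
boundaries configurable), and a histogram in 1 mm substrata centred on
integer millimetres (bin k covers [k−½, k+½) mm).  Class fractions are
always computed from the raw margins, never re-derived from bins.
Excluded voxels are removed from the denominator — they are not counted as
margin 0 — so exclusion renormalises the class fractions.

On-lattice margins are square roots of integer combinations, so raw
percentiles carry irrational values (√2, √5, …).  The summary therefore
also contains a **substrata distance summary**: the same five order
statistics computed after rounding each margin to its substrata centre.
This is the whole-millimetre description of the distribution that matches
the histogram, and it is the scale on which the reference distance
summaries of the artificial cases are stated.

## Phantoms

The sphere phantoms define the verification conditions; their geometry is
fixed and must not drift, since the exact voxel counts are part of the
expected values.  Spheres are closed balls on voxel centres (foreground
iff |centre − c| ≤ d/2), dimensions are diameters, the default grid is
64³ at 1 mm isotropic spacing with structures centred on a voxel.  A
10 mm tumor rasterized this way has exactly 222 contour voxels — the
denominator behind all reference percentages.

* **T1.6** — tumor ∅ 10 mm; ablation ∅ 15 mm, centre offset laterally in
  x and y.  The offset is a parameter; its default (3, 3, 0) mm is pinned
  so the case reproduces the published reference distribution (27.93 % /
  62.16 % / 9.91 % classes; margins −√5 … 6.63 mm raw, −2 … 7 mm with
  whole-millimetre quartiles −1 / 1 / 3).  A literal (5, 5, 0) mm offset
  does not reproduce that distribution under any rasterization examined.
* **T2.2** — subcapsular tumor ∅ 10 mm fully covered by an ablation
  ∅ 15 mm; the liver capsule is a sphere ∅ 60 mm internally tangent to
  the tumor, and the ablation centre is shifted 1.5 mm away from the
  capsule (any shift in 1.5–1.7 mm gives the same voxel counts).  Without
  exclusion the class fractions are 98.20 % / 1.80 % (yellow/green); the
  5 mm exclusion removes 125 of 222 surface voxels and renormalises them
  to 95.88 % / 4.12 %.  The liver sphere is allowed to be clipped by the
  grid, like a local capsule segmentation patch.
* **Random blobs** — seeded, irregular, overlapping tumor/ablation shapes
  (a shared central ball guaranteeing overlap, plus smoothed thresholded
  noise) used for oracle tests at arbitrary spacings.
* A planar half-space "liver" is provided for analytically checkable
  exclusion tests.

What the phantoms do *not* emulate: irregular clinical ablation shapes,
segmentation noise, registration error, tissue shrinkage after microwave
ablation, or heat-sink effects near vessels.  Passing phantom tests
validates the geometry pipeline, not the clinical segmentation workflow
around it.

## Numerical choices

* Distances are voxel-centre to voxel-centre; no sub-voxel surface
  interpolation.  `scipy.ndimage.distance_transform_edt` with
  `sampling=spacing` provides the exact transform; the test suite checks
  it voxel-for-voxel against a brute-force all-pairs oracle (agreement to
  the last few floating-point digits; signs exactly).
* Exclusion is strict (`< threshold`), so threshold 0 excludes nothing; a
  voxel exactly at the threshold distance is kept.
* If every tumor surface voxel is excluded, the package raises a dedicated
  error naming the small-subcapsular-tumor limitation instead of returning
  an empty distribution.
* The requirement that the liver patch extend at least the exclusion
  threshold beyond the tumor is checked heuristically (warning only): a
  side of the threshold-expanded tumor box is accepted when the liver
  reaches past it, reaches the grid border, or its contour passes through
  the window there (a genuine capsule).  A strict check is impossible
  because a too-small liver patch is indistinguishable from a real capsule
  at the same location.
* 3-D projection: every ablation-surface voxel receives the margin of its
  nearest included tumor-surface voxel (spacing-aware), ties resolved
  toward the smallest margin, so orange regions on the ablation surface
  always correspond to actually uncovered tumor.  This projection rule is
  this package's definition.
* Mesh output is legacy-VTK ASCII polydata (point cloud with per-vertex
  `qam_mm` float and `qam_class` int fields) written directly — a small,
  dependency-free text format readable by VTK-based viewers.

## Problem sizes

Tests and the acceptance script run on 24³–64³ grids; a full phantom case
(load, margins, summary, histogram, mesh) completes in well under a second
on one CPU, and the complete verification suite in a few seconds.

## Known limitations

* Margins are lattice distances; at coarse spacing the ±half-voxel
  boundary placement (the difference between the two conventions) is a
  visible fraction of a 5 mm margin.
* Geodesic (within-liver) distances, mesh-based surface distances and
  vessel/heat-sink exclusion volumes are out of scope.
* The subcapsular exclusion removes voxels; it never reclassifies them as
  covered, deliberately avoiding overestimated completeness — with the
  corollary that very small subcapsular tumors yield no distances at all.
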