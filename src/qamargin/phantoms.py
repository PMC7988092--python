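"""Artificial sphere cases standing in for clinical data.

Verification of the margin pipeline uses programmatically generated
spheres emulating tumors, ablation zones and the liver capsule, so every
expected number can be checked against manual computation.  Two named
cases are provided:

``T1.6``
    A 10 mm tumor ablated with a 15 mm ablation zone whose centre is
    shifted laterally in x and y, leaving a crescent of tumor surface with
    negative margins.  The default shift of (3, 3, 0) mm is pinned so that
    the case reproduces the published reference distribution for this
    scenario (28 % of the tumor surface uncovered, margins from -sqrt(5)
    to ~7 mm) under the ``interface`` distance convention.

``T2.2``
    A subcapsular 10 mm tumor fully covered by a 15 mm ablation zone,
    with a spherical liver capsule tangent to the tumor.  Used to compare
    margin distributions with and without the subcapsular exclusion
    volume.

Spheres are rasterized as closed balls on voxel centres: a voxel is
foreground iff its centre lies within ``diameter/2`` of the sphere centre
(in mm).  Dimensions are diameters.  The rule must stay fixed: the exact
voxel counts of the named cases are part of their definition.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io_model import AblationCase, SegmentationMask

__all__ = [
    "PhantomSpec",
    "rasterize_sphere",
    "rasterize_half_space",
    "make_case_T16",
    "make_case_T22",
    "make_subcapsular_planar_case",
    "make_random_blob_case",
    "NAMED_CASES",
]

DEFAULT_GRID = (64, 64, 64)
DEFAULT_SPACING = (1.0, 1.0, 1.0)


@dataclass(frozen=True)
class PhantomSpec:
    """Declarative description of a sphere phantom case."""

    grid_shape: tuple[int, int, int] = DEFAULT_GRID
    spacing: tuple[float, float, float] = DEFAULT_SPACING
    tumor_center: tuple[float, float, float] = (32.0, 32.0, 32.0)
    tumor_diameter: float = 10.0
    ablation_center: tuple[float, float, float] = (32.0, 32.0, 32.0)
    ablation_diameter: float = 15.0
    liver_center: tuple[float, float, float] | None = None
    liver_diameter: float | None = None
    case_id: str = "phantom"

    def build(self) -> AblationCase:
        tumor = rasterize_sphere(
            self.tumor_center, self.tumor_diameter, self.grid_shape, self.spacing, "tumor"
        )
        ablation = rasterize_sphere(
            self.ablation_center, self.ablation_diameter, self.grid_shape,
            self.spacing, "ablation",
        )
        liver = None
        if self.liver_center is not None:
            liver = rasterize_sphere(
                self.liver_center, self.liver_diameter, self.grid_shape,
                self.spacing, "liver", clip=True,
            )
        return AblationCase(tumor=tumor, ablation=ablation, liver=liver,
                            case_id=self.case_id)


def _voxel_center_distance2(center, grid_shape, spacing):
    idx = np.indices(grid_shape, dtype=float)
    return sum(
        ((idx[a] * spacing[a] - center[a]) ** 2) for a in range(3)
    )


def rasterize_sphere(
    center,
    diameter: float,
    grid_shape=DEFAULT_GRID,
    spacing=DEFAULT_SPACING,
    role: str = "tumor",
    clip: bool = False,
) -> SegmentationMask:
    """Closed ball on voxel centres: foreground iff |c_voxel - c| <= d/2.

    ``center`` is in mm (voxel centre coordinates are ``index * spacing``).
    Unless ``clip`` is set, the sphere must fit inside the grid; the liver
    capsule phantom is allowed to be clipped at the volume border, like a
    local liver segmentation patch.
    """
    if diameter <= 0:
        raise ValueError(f"sphere diameter must be positive, got {diameter}")
    r = diameter / 2.0
    if not clip:
        extent = (np.asarray(grid_shape) - 1) * np.asarray(spacing)
        c = np.asarray(center, dtype=float)
        if (c - r < 0).any() or (c + r > extent).any():
            raise ValueError(
                f"sphere centre {tuple(c)} mm, diameter {diameter} mm does not "
                f"fit inside the grid extent {tuple(extent)} mm"
            )
    vox = _voxel_center_distance2(center, grid_shape, spacing) <= r * r
    return SegmentationMask(voxels=vox, spacing=tuple(spacing), role=role)


def rasterize_half_space(
    axis: int,
    offset_mm: float,
    grid_shape=DEFAULT_GRID,
    spacing=DEFAULT_SPACING,
    role: str = "liver",
    positive_side: bool = False,
) -> SegmentationMask:
    """Half-space mask: voxels with centre coordinate <= offset along ``axis``
    (or >= with ``positive_side``).  A planar liver boundary for analytically
    checkable exclusion tests."""
    idx = np.indices(grid_shape, dtype=float)[axis] * spacing[axis]
    vox = idx >= offset_mm if positive_side else idx <= offset_mm
    return SegmentationMask(voxels=vox, spacing=tuple(spacing), role=role)


def make_case_T16(
    offset_mm: tuple[float, float, float] = (3.0, 3.0, 0.0),
    grid_shape=DEFAULT_GRID,
    spacing=DEFAULT_SPACING,
) -> AblationCase:
    """Case T1.6: 10 mm tumor, 15 mm ablation shifted laterally in x and y.

    The ablation centre is displaced by ``offset_mm`` relative to the tumor
    centre; the default (3, 3, 0) reproduces the reference margin
    distribution for this case (see module docstring).  No liver mask.
    """
    center = tuple(((np.asarray(grid_shape) // 2) * np.asarray(spacing)).astype(float))
    spec = PhantomSpec(
        grid_shape=tuple(grid_shape),
        spacing=tuple(spacing),
        tumor_center=center,
        tumor_diameter=10.0,
        ablation_center=tuple(np.asarray(center) + np.asarray(offset_mm, dtype=float)),
        ablation_diameter=15.0,
        case_id="T1.6",
    )
    return spec.build()


def make_case_T22(
    ablation_shift_mm: float = 1.5,
    liver_diameter: float = 60.0,
    grid_shape=DEFAULT_GRID,
    spacing=DEFAULT_SPACING,
) -> AblationCase:
    """Case T2.2: subcapsular 10 mm tumor fully covered by a 15 mm ablation.

    The liver capsule is a large sphere internally tangent to the tumor at
    its +x pole; the ablation centre is shifted ``ablation_shift_mm`` away
    from the capsule (toward the liver interior) along x, keeping the whole
    tumor covered while part of the deep tumor surface reaches >= 5 mm
    margins.  The defaults reproduce the reference class fractions with and
    without the exclusion volume.
    """
    center = np.asarray(
        ((np.asarray(grid_shape) // 2) * np.asarray(spacing)).astype(float)
    )
    rl = liver_diameter / 2.0
    spec = PhantomSpec(
        grid_shape=tuple(grid_shape),
        spacing=tuple(spacing),
        tumor_center=tuple(center),
        tumor_diameter=10.0,
        ablation_center=tuple(center - np.array([ablation_shift_mm, 0.0, 0.0])),
        ablation_diameter=15.0,
        liver_center=tuple(center - np.array([rl - 5.0, 0.0, 0.0])),
        liver_diameter=liver_diameter,
        case_id="T2.2",
    )
    case = spec.build()
    if (case.tumor.voxels & ~case.ablation.voxels).any():
        raise ValueError("T2.2 construction error: ablation does not cover the tumor")
    return case


def make_subcapsular_planar_case(
    gap_mm: float = 0.0,
    grid_shape=(48, 48, 48),
    spacing=DEFAULT_SPACING,
) -> AblationCase:
    """Subcapsular variant with a planar liver boundary, ``gap_mm`` between
    the tumor surface and the capsule plane.  Analytically checkable."""
    center = np.asarray(
        ((np.asarray(grid_shape) // 2) * np.asarray(spacing)).astype(float)
    )
    tumor = rasterize_sphere(tuple(center), 10.0, grid_shape, spacing, "tumor")
    ablation = rasterize_sphere(tuple(center), 15.0, grid_shape, spacing, "ablation")
    plane = center[0] + 5.0 + gap_mm
    liver = rasterize_half_space(0, plane, grid_shape, spacing, "liver")
    return AblationCase(tumor=tumor, ablation=ablation, liver=liver,
                        case_id=f"planar-subcapsular-{gap_mm:g}mm")


def make_random_blob_case(
    seed: int,
    max_extent: int = 32,
    spacing=DEFAULT_SPACING,
    with_liver: bool = False,
) -> AblationCase:
    """Seeded irregular tumor/ablation blobs for brute-force oracle tests.

    Both blobs are unions of a shared central ball (guaranteeing overlap
    and non-emptiness) with smoothed random noise, so shapes are irregular
    but reproducible for a given seed.
    """
    from scipy import ndimage

    rng = np.random.default_rng(seed)
    shape = (max_extent,) * 3
    center = (np.asarray(shape) // 2) * np.asarray(spacing)

    def blob(extra_radius: float, thresh_q: float) -> np.ndarray:
        noise = ndimage.gaussian_filter(rng.normal(size=shape), sigma=2.5)
        core = _voxel_center_distance2(center, shape, spacing) <= extra_radius**2
        mask = core | (noise > np.quantile(noise, thresh_q))
        # keep away from the border so erosion/EDT see real background
        interior = np.zeros(shape, dtype=bool)
        interior[2:-2, 2:-2, 2:-2] = True
        return mask & interior

    smin = float(min(spacing))
    tumor_vox = blob(3.0 * smin, 0.97)
    abl_vox = blob(4.0 * smin, 0.94)
    tumor = SegmentationMask(voxels=tumor_vox, spacing=tuple(spacing), role="tumor")
    ablation = SegmentationMask(voxels=abl_vox, spacing=tuple(spacing), role="ablation")
    liver = None
    if with_liver:
        liver_vox = ndimage.binary_dilation(tumor_vox | abl_vox, iterations=3)
        liver = SegmentationMask(voxels=liver_vox, spacing=tuple(spacing), role="liver")
    return AblationCase(
        tumor=tumor, ablation=ablation, liver=liver, case_id=f"blob-{seed}"
    )


NAMED_CASES = {
    "T1.6": make_case_T16,
    "T2.2": make_case_T22,
}
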