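"""Surface extraction, signed distance maps and margin extraction.

The quantitative ablation margin (QAM) of a treated liver tumor is the
signed Euclidean distance from each tumor surface voxel to the ablation
boundary: positive where the tumor surface lies inside the ablation zone
(covered, with that much necrosis margin) and negative where it lies
outside (residual uncovered tumor).  Distances are exact Euclidean
distances between voxel centers, weighted by the voxel spacing, so fully
anisotropic grids are supported.

Two conventions for the zero set of the distance transform are provided:

``zero_set="surface"`` (default)
    Distances are measured to the one-voxel-thin, face-connected contour of
    the ablation mask (mask minus its 6-connected erosion).  Contour voxels
    map to exactly 0, so a tumor surface voxel that coincides with the
    ablation contour has margin 0 and identical masks give margin 0
    everywhere.

``zero_set="interface"``
    The classical signed Euclidean distance transform of a binary mask,
    ``edt(mask) - edt(~mask)``: each voxel's distance to the nearest voxel
    of the opposite phase.  The implied boundary lies between voxel
    centers, so magnitudes are at least one voxel step and identical masks
    give +1-voxel margins on the contour.  The published reference values
    for the artificial sphere cases follow this convention.

Subcapsular tumors: tumor surface voxels closer than a threshold (default
5 mm) to the liver surface are excluded from the margin distribution, since
a circumferential margin is anatomically impossible against the liver
capsule and would otherwise be reported as insufficient coverage.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .io_model import (
    AblationCase,
    AllExcludedError,
    EmptyStructureError,
    MissingLiverError,
    SegmentationMask,
)

__all__ = [
    "SurfaceVoxelSet",
    "SignedDistanceMap",
    "MarginDistribution",
    "extract_surface",
    "signed_distance_map",
    "exclude_subcapsular",
    "compute_margins",
    "DEFAULT_EXCLUSION_MM",
    "ZERO_SETS",
]

#: Exclusion volume threshold below the liver capsule, in mm.  5 mm follows
#: the accepted definition of a minimal complete-ablation margin; it can be
#: adapted to individual treatment targets.
DEFAULT_EXCLUSION_MM = 5.0

ZERO_SETS = ("surface", "interface")

# 6-connected (face-connectivity) structuring element: a voxel survives
# erosion iff all six face neighbors are foreground.
_STRUCT = ndimage.generate_binary_structure(3, 1)


@dataclass(frozen=True)
class SurfaceVoxelSet:
    """The one-voxel-thin, face-connected contour of a binary mask."""

    mask: np.ndarray  # boolean grid, True on surface voxels
    parent_shape: tuple[int, int, int]
    parent_spacing: tuple[float, float, float]
    role: str

    @property
    def indices(self) -> np.ndarray:
        """(N, 3) voxel indices in lexicographic order."""
        return np.argwhere(self.mask)

    def __len__(self) -> int:
        return int(self.mask.sum())


@dataclass(frozen=True)
class SignedDistanceMap:
    """Per-voxel signed distance (mm) to the ablation boundary.

    Negative on ablation background, positive (or zero for the ``surface``
    convention) on ablation foreground.
    """

    values: np.ndarray
    spacing: tuple[float, float, float]
    zero_set: str = "surface"


@dataclass(frozen=True)
class MarginDistribution:
    """Signed margins of the included tumor surface voxels.

    ``margins[i]`` is the margin of ``included.indices[i]``; voxels removed
    by the subcapsular exclusion are listed in ``excluded``.
    """

    margins: np.ndarray
    included: SurfaceVoxelSet
    excluded: np.ndarray = field(default_factory=lambda: np.empty((0, 3), dtype=np.int64))
    exclusion_threshold: float | None = None
    zero_set: str = "surface"

    @property
    def n_included(self) -> int:
        return int(self.margins.size)

    @property
    def n_excluded(self) -> int:
        return int(len(self.excluded))


def extract_surface(mask: SegmentationMask) -> SurfaceVoxelSet:
    """Contour of a mask: foreground minus its face-connected erosion.

    A voxel is on the surface iff it is foreground and at least one of its
    six face neighbors (or the outside of the grid) is background.  The
    6-connected structuring element keeps the contour one voxel thin while
    retaining corner voxels along large edges.
    """
    if mask.is_empty():
        raise EmptyStructureError(f"{mask.role} mask is empty; no surface to extract")
    eroded = ndimage.binary_erosion(mask.voxels, _STRUCT, border_value=0)
    return SurfaceVoxelSet(
        mask=mask.voxels & ~eroded,
        parent_shape=mask.shape,
        parent_spacing=mask.spacing,
        role=mask.role,
    )


def signed_distance_map(
    ablation: SegmentationMask, zero_set: str = "surface"
) -> SignedDistanceMap:
    """Exact signed Euclidean distance map of the ablation mask.

    Distances are between voxel centers and use the voxel spacing along
    each axis (exact transform, not a chamfer approximation).  Background
    voxels are negated so that uncovered tumor reads as a negative margin.
    """
    if zero_set not in ZERO_SETS:
        raise ValueError(f"zero_set must be one of {ZERO_SETS}, got {zero_set!r}")
    fg = ablation.voxels
    spacing = ablation.spacing
    if zero_set == "surface":
        surface = extract_surface(ablation).mask
        dist = ndimage.distance_transform_edt(~surface, sampling=spacing)
        values = np.where(fg, dist, -dist)
    else:
        if not fg.any():
            raise EmptyStructureError("ablation mask is empty")
        dist_in = ndimage.distance_transform_edt(fg, sampling=spacing)
        dist_out = ndimage.distance_transform_edt(~fg, sampling=spacing)
        values = dist_in - dist_out
    return SignedDistanceMap(values=values, spacing=spacing, zero_set=zero_set)


def _surface_distance_at(
    points_mask: np.ndarray, target_surface: np.ndarray, spacing
) -> np.ndarray:
    """Distance from each True voxel of ``points_mask`` to the target surface."""
    dist = ndimage.distance_transform_edt(~target_surface, sampling=spacing)
    return dist[points_mask]


def exclude_subcapsular(
    tumor_surface: SurfaceVoxelSet,
    liver: SegmentationMask,
    threshold: float = DEFAULT_EXCLUSION_MM,
) -> tuple[SurfaceVoxelSet, np.ndarray]:
    """Split the tumor surface at the subcapsular exclusion threshold.

    Tumor surface voxels strictly closer than ``threshold`` mm to the liver
    surface (the face-connected contour of the liver mask) are excluded;
    the rest are returned as the included surface.  Exclusion is strict
    ("closer than"), so ``threshold=0`` excludes nothing.
    """
    if liver.is_empty():
        raise EmptyStructureError("liver mask is empty; cannot exclude subcapsular voxels")
    ts = tumor_surface.mask
    if (ts & ~liver.voxels).any():
        warnings.warn(
            "tumor surface voxels lie outside the liver mask; the liver "
            "segmentation may not surround the tumor",
            stacklevel=2,
        )
    _check_liver_extent(tumor_surface, liver, threshold)
    liver_surface = extract_surface(liver).mask
    dist = _surface_distance_at(ts, liver_surface, liver.spacing)
    excluded_flags = dist < threshold
    idx = np.argwhere(ts)
    excluded = idx[excluded_flags]
    included_mask = ts.copy()
    included_mask[tuple(excluded.T)] = False
    if not included_mask.any():
        raise AllExcludedError(
            "all tumor surface voxels lie closer than "
            f"{threshold:g} mm to the liver surface; for such small "
            "subcapsular tumors every voxel is subtracted from the analysis "
            "and no surface distances can be yielded"
        )
    included = SurfaceVoxelSet(
        mask=included_mask,
        parent_shape=tumor_surface.parent_shape,
        parent_spacing=tumor_surface.parent_spacing,
        role=tumor_surface.role,
    )
    return included, excluded


def _check_liver_extent(
    tumor_surface: SurfaceVoxelSet, liver: SegmentationMask, threshold: float
) -> None:
    """Warn when the liver patch looks smaller than tumor + threshold.

    The liver segmentation should extend at least the exclusion threshold
    beyond the tumor so that only genuinely subcapsular voxels are removed.
    A side of the expanded tumor box is considered fine when the liver
    reaches past it, reaches the grid border, or its surface (the capsule)
    passes through the window on that side.
    """
    tidx = tumor_surface.indices
    lidx = np.argwhere(liver.voxels)
    shape = np.asarray(liver.shape)
    pad = np.ceil(threshold / np.asarray(liver.spacing)).astype(int)
    t_lo, t_hi = tidx.min(axis=0), tidx.max(axis=0)
    l_lo, l_hi = lidx.min(axis=0), lidx.max(axis=0)
    liver_surface = None
    for ax in range(3):
        for side, need, have, border_ok in (
            ("low", t_lo[ax] - pad[ax], l_lo[ax], l_lo[ax] == 0),
            ("high", t_hi[ax] + pad[ax], l_hi[ax], l_hi[ax] == shape[ax] - 1),
        ):
            ok = (have <= need) if side == "low" else (have >= need)
            if ok or border_ok:
                continue
            if liver_surface is None:
                liver_surface = extract_surface(liver).mask
            window = [slice(int(t_lo[a]), int(t_hi[a]) + 1) for a in range(3)]
            if side == "low":
                window[ax] = slice(int(max(need, 0)), int(t_lo[ax]) + 1)
            else:
                window[ax] = slice(int(t_hi[ax]), int(min(need, shape[ax] - 1)) + 1)
            if liver_surface[tuple(window)].any():
                continue  # real capsule inside the window on this side
            warnings.warn(
                f"liver mask extends less than {threshold:g} mm beyond the "
                f"tumor on axis {ax} ({side} side); subcapsular exclusion "
                "may remove voxels that are not below the capsule",
                stacklevel=3,
            )
            return


def compute_margins(
    case: AblationCase,
    threshold: float = DEFAULT_EXCLUSION_MM,
    use_exclusion: bool = False,
    zero_set: str = "surface",
) -> MarginDistribution:
    """Signed margins at every (included) tumor surface voxel.

    The signed ablation distance map is sampled at the tumor contour
    voxels; with ``use_exclusion`` the subcapsular exclusion is applied
    first, which requires a liver mask in the case.
    """
    tumor_surface = extract_surface(case.tumor)
    if use_exclusion:
        if case.liver is None:
            raise MissingLiverError(
                f"case {case.case_id!r}: subcapsular exclusion requested but "
                "no liver mask is present"
            )
        included, excluded = exclude_subcapsular(tumor_surface, case.liver, threshold)
        excl_threshold = threshold
    else:
        included = tumor_surface
        excluded = np.empty((0, 3), dtype=np.int64)
        excl_threshold = None
    sdm = signed_distance_map(case.ablation, zero_set=zero_set)
    margins = sdm.values[included.mask]
    return MarginDistribution(
        margins=margins,
        included=included,
        excluded=excluded,
        exclusion_threshold=excl_threshold,
        zero_set=zero_set,
    )
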