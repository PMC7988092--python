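"""Loading, validation and cropping of per-case segmentation masks.

Quantitative ablation margin (QAM) computation expects, per case, binary
segmentation masks of the tumor, the ablation zone and (for subcapsular
tumors) the surrounding liver, all co-registered and resampled onto one
voxel grid.  This module enforces that input contract: masks must be
binary, share grid shape and voxel spacing, and the tumor and ablation
structures must be non-empty.  Registration and resampling themselves are
prerequisites performed upstream; nothing here resamples.

All computation downstream works on 0-based voxel indices plus the spacing
vector; the NIfTI affine is carried along only so that derived masks can be
written back into the original physical frame.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import nibabel as nib
import numpy as np

__all__ = [
    "QAMError",
    "RegistrationContractError",
    "EmptyStructureError",
    "NonBinaryMaskError",
    "MissingLiverError",
    "AllExcludedError",
    "SegmentationMask",
    "AblationCase",
    "load_mask",
    "load_case",
    "save_mask",
    "crop_to_union_bbox",
]

ROLES = ("tumor", "ablation", "liver")

#: Padding (in voxels) kept around the union bounding box when cropping.
#: Two voxels of background guarantee that face-connected erosion and the
#: distance transform near the crop border equal the uncropped result.
DEFAULT_PAD_VOXELS = 2


class QAMError(Exception):
    """Base class for QAM contract violations."""


class RegistrationContractError(QAMError):
    """Masks do not share grid shape and voxel spacing (requirement iii)."""


class EmptyStructureError(QAMError):
    """A structure that must contain foreground voxels is empty."""


class NonBinaryMaskError(QAMError):
    """A mask volume contains values other than {0, 1}."""


class MissingLiverError(QAMError):
    """Subcapsular exclusion requested without a liver mask."""


class AllExcludedError(QAMError):
    """Every tumor surface voxel fell inside the subcapsular exclusion volume.

    This is the documented limitation for very small subcapsular tumors: when
    the whole tumor lies closer to the liver capsule than the exclusion
    threshold, all tumor surface voxels are subtracted from the analysis and
    no surface distances can be reported.
    """


@dataclass(frozen=True)
class SegmentationMask:
    """One binary voxel grid with spacing metadata.

    Parameters
    ----------
    voxels
        Boolean 3-D array; ``True`` is structure foreground.
    spacing
        Physical size of one voxel along each axis, in mm.
    role
        One of ``"tumor"``, ``"ablation"``, ``"liver"``.
    affine
        Optional 4x4 voxel-to-world matrix, carried through for output
        writing only; computation uses indices and spacing.
    source_path
        Where the mask was read from, if anywhere.
    """

    voxels: np.ndarray
    spacing: tuple[float, float, float]
    role: str
    affine: np.ndarray | None = field(default=None, compare=False)
    source_path: str | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        vox = np.asarray(self.voxels)
        if vox.ndim != 3:
            raise NonBinaryMaskError(
                f"{self.role}: expected a 3-D volume, got {vox.ndim}-D"
            )
        if vox.dtype != bool:
            vals = np.unique(vox)
            if not np.isin(vals, (0, 1)).all():
                raise NonBinaryMaskError(
                    f"{self.role}: mask values {vals[:8]} are not binary"
                )
            vox = vox.astype(bool)
        object.__setattr__(self, "voxels", vox)
        spacing = tuple(float(s) for s in self.spacing)
        if len(spacing) != 3 or any(s <= 0 for s in spacing):
            raise QAMError(f"{self.role}: spacing must be three positive mm values")
        object.__setattr__(self, "spacing", spacing)
        if self.role not in ROLES:
            raise QAMError(f"unknown mask role {self.role!r}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape

    @property
    def n_foreground(self) -> int:
        return int(self.voxels.sum())

    def is_empty(self) -> bool:
        return not self.voxels.any()


@dataclass(frozen=True)
class AblationCase:
    """Tumor + ablation (+ optional liver) masks on one common grid."""

    tumor: SegmentationMask
    ablation: SegmentationMask
    liver: SegmentationMask | None
    case_id: str = ""

    def __post_init__(self) -> None:
        masks = self.masks()
        ref = masks[0]
        for m in masks[1:]:
            if m.shape != ref.shape:
                raise RegistrationContractError(
                    f"case {self.case_id!r}: {m.role} grid {m.shape} differs "
                    f"from {ref.role} grid {ref.shape}; masks must be "
                    "co-registered and resampled to identical dimensions"
                )
            if not np.allclose(m.spacing, ref.spacing, rtol=0, atol=1e-4):
                raise RegistrationContractError(
                    f"case {self.case_id!r}: {m.role} spacing {m.spacing} "
                    f"differs from {ref.role} spacing {ref.spacing}"
                )
        for m in masks:
            if m.role != "liver" and m.is_empty():
                raise EmptyStructureError(
                    f"case {self.case_id!r}: {m.role} mask has no foreground"
                )
        if self.liver is not None and self.liver.is_empty():
            raise EmptyStructureError(
                f"case {self.case_id!r}: liver mask has no foreground"
            )
        affines = [m.affine for m in masks if m.affine is not None]
        for a in affines[1:]:
            if not np.allclose(a, affines[0], atol=1e-3):
                warnings.warn(
                    f"case {self.case_id!r}: masks share the grid but carry "
                    "different affines; computation proceeds on voxel indices",
                    stacklevel=2,
                )
                break

    def masks(self) -> tuple[SegmentationMask, ...]:
        out = [self.tumor, self.ablation]
        if self.liver is not None:
            out.append(self.liver)
        return tuple(out)

    @property
    def spacing(self) -> tuple[float, float, float]:
        return self.tumor.spacing

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.tumor.shape


def _binarize(data: np.ndarray, role: str, path) -> np.ndarray:
    # Float-stored binaries (0.0/1.0) are accepted via the >0.5 threshold;
    # anything with additional label values is rejected outright.
    finite = np.isfinite(data)
    if not finite.all():
        raise NonBinaryMaskError(f"{role} mask {path}: non-finite voxel values")
    vals = np.unique(data)
    if not np.isin(np.round(vals, 6), (0.0, 1.0)).all():
        raise NonBinaryMaskError(
            f"{role} mask {path}: values {vals[:8]} are not binary {{0,1}}"
        )
    return data > 0.5


def load_mask(path, role: str) -> SegmentationMask:
    """Read one NIfTI volume as a binary segmentation mask."""
    path = Path(path)
    try:
        img = nib.load(str(path))
        data = np.asarray(img.get_fdata())
    except NonBinaryMaskError:
        raise
    except Exception as exc:  # unreadable / corrupt file
        raise OSError(f"cannot read {role} mask from {path}: {exc}") from exc
    if data.ndim == 4 and data.shape[3] == 1:
        data = data[..., 0]
    vox = _binarize(data, role, path)
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    return SegmentationMask(
        voxels=vox,
        spacing=spacing,
        role=role,
        affine=np.asarray(img.affine, dtype=float),
        source_path=str(path),
    )


def load_case(
    tumor_path,
    ablation_path,
    liver_path=None,
    case_id: str = "",
) -> AblationCase:
    """Load and validate the 2-3 masks of one ablation case."""
    tumor = load_mask(tumor_path, "tumor")
    ablation = load_mask(ablation_path, "ablation")
    liver = load_mask(liver_path, "liver") if liver_path is not None else None
    if not case_id:
        case_id = Path(tumor_path).name.split(".")[0]
    return AblationCase(tumor=tumor, ablation=ablation, liver=liver, case_id=case_id)


def save_mask(mask: SegmentationMask, path) -> Path:
    """Write a mask as NIfTI (uint8), preserving spacing and affine."""
    path = Path(path)
    affine = mask.affine
    if affine is None:
        affine = np.diag((*mask.spacing, 1.0))
    img = nib.Nifti1Image(mask.voxels.astype(np.uint8), affine)
    img.header.set_zooms(mask.spacing)
    nib.save(img, str(path))
    return path


def _union_bbox(masks) -> tuple[np.ndarray, np.ndarray]:
    lo = np.full(3, np.iinfo(np.int64).max)
    hi = np.full(3, -1)
    for m in masks:
        idx = np.argwhere(m.voxels)
        if idx.size:
            lo = np.minimum(lo, idx.min(axis=0))
            hi = np.maximum(hi, idx.max(axis=0))
    return lo, hi


def crop_to_union_bbox(case: AblationCase, pad: int = DEFAULT_PAD_VOXELS) -> AblationCase:
    """Crop all masks to the union bounding box plus ``pad`` background voxels.

    An optional speed-up: the padded sub-volume contains every foreground
    voxel of every mask, so surface extraction and the distance transform
    sampled on the structures are identical to the uncropped computation.
    ``pad`` below 2 voxels would break that guarantee and is rejected.
    """
    if pad < 2:
        raise ValueError(f"pad must be >= 2 voxels to preserve results, got {pad}")
    lo, hi = _union_bbox(case.masks())
    shape = np.asarray(case.shape)
    lo = np.maximum(lo - pad, 0)
    hi = np.minimum(hi + pad, shape - 1)
    sl = tuple(slice(int(a), int(b) + 1) for a, b in zip(lo, hi))

    def crop(mask: SegmentationMask) -> SegmentationMask:
        affine = mask.affine
        if affine is not None:
            affine = affine.copy()
            affine[:3, 3] += affine[:3, :3] @ lo
        return replace(mask, voxels=mask.voxels[sl], affine=affine)

    return AblationCase(
        tumor=crop(case.tumor),
        ablation=crop(case.ablation),
        liver=crop(case.liver) if case.liver is not None else None,
        case_id=case.case_id,
    )
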