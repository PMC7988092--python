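"""Shared fixtures and brute-force oracles.

The oracles recompute margins by explicit all-pairs distance minimisation
over voxel index sets (``argwhere`` + ``cdist``), independently of the
distance-transform path they are used to check.
"""

from __future__ import annotations

import numpy as np
import pytest
from scipy.spatial.distance import cdist

from qamargin import (
    AblationCase,
    SegmentationMask,
    extract_surface,
    make_case_T16,
    make_case_T22,
)


def brute_force_margins(case: AblationCase, zero_set: str = "surface") -> np.ndarray:
    """All-pairs oracle for the signed margins at tumor surface voxels.

    ``surface``: magnitude is the minimum distance to an ablation contour
    voxel.  ``interface``: magnitude is the minimum distance to a voxel of
    the opposite ablation phase.  Sign is negative iff the tumor surface
    voxel is ablation background.
    """
    spacing = np.asarray(case.spacing)
    tum_idx = extract_surface(case.tumor).indices
    pts = tum_idx * spacing
    abl = case.ablation.voxels
    inside = abl[tuple(tum_idx.T)]
    if zero_set == "surface":
        target = np.argwhere(extract_surface(case.ablation).mask) * spacing
        mag = cdist(pts, target).min(axis=1)
    else:
        fg_pts = np.argwhere(abl) * spacing
        bg_pts = np.argwhere(~abl) * spacing
        mag = np.where(
            inside,
            cdist(pts, bg_pts).min(axis=1),
            cdist(pts, fg_pts).min(axis=1),
        )
    return np.where(inside, mag, -mag)


def assert_margins_equal(got: np.ndarray, want: np.ndarray) -> None:
    """Exact agreement between the EDT path and the all-pairs oracle.

    Both routes find the same minimising voxel; their magnitudes may differ
    in the last couple of floating-point digits because the three squared
    terms are summed in different orders.  Signs must match exactly.
    """
    got = np.asarray(got)
    want = np.asarray(want)
    assert got.shape == want.shape
    assert np.array_equal(np.sign(got), np.sign(want))
    assert np.all(np.abs(got - want) <= 8 * np.spacing(np.maximum(np.abs(want), 1.0)))


def brute_force_excluded(case: AblationCase, threshold: float) -> np.ndarray:
    """Oracle for the subcapsular exclusion: boolean flag per tumor
    surface voxel, True when strictly closer than ``threshold`` mm to the
    liver contour."""
    spacing = np.asarray(case.spacing)
    tum_pts = extract_surface(case.tumor).indices * spacing
    liv_pts = np.argwhere(extract_surface(case.liver).mask) * spacing
    return cdist(tum_pts, liv_pts).min(axis=1) < threshold


def cube_case(side: int = 5, pad: int = 4, spacing=(1.0, 1.0, 1.0)) -> AblationCase:
    """Tumor == ablation == a solid cube; margins are all zero by identity."""
    shape = (side + 2 * pad,) * 3
    vox = np.zeros(shape, dtype=bool)
    vox[pad : pad + side, pad : pad + side, pad : pad + side] = True
    tumor = SegmentationMask(voxels=vox, spacing=spacing, role="tumor")
    ablation = SegmentationMask(voxels=vox.copy(), spacing=spacing, role="ablation")
    return AblationCase(tumor=tumor, ablation=ablation, liver=None, case_id="cube")


@pytest.fixture(scope="session")
def t16_case() -> AblationCase:
    return make_case_T16()


@pytest.fixture(scope="session")
def t22_case() -> AblationCase:
    return make_case_T22()
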