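"""Geometry core: surfaces, signed distances, exclusion, margins."""

import numpy as np
import pytest

from qamargin import (
    AblationCase,
    AllExcludedError,
    EmptyStructureError,
    MissingLiverError,
    SegmentationMask,
    compute_margins,
    exclude_subcapsular,
    extract_surface,
    make_random_blob_case,
    make_subcapsular_planar_case,
    rasterize_half_space,
    rasterize_sphere,
    signed_distance_map,
)

from conftest import (
    assert_margins_equal,
    brute_force_excluded,
    brute_force_margins,
    cube_case,
)


def _cube_mask(side, pad=3, spacing=(1.0, 1.0, 1.0), role="tumor"):
    shape = (side + 2 * pad,) * 3
    vox = np.zeros(shape, dtype=bool)
    vox[pad : pad + side, pad : pad + side, pad : pad + side] = True
    return SegmentationMask(voxels=vox, spacing=spacing, role=role)


@pytest.mark.parametrize(
    ("side", "expected"),
    [(1, 1), (2, 8), (3, 26), (5, 98)],
)
def test_surface_count_of_solid_cubes(side, expected):
    """A voxel survives 6-connected erosion iff all face neighbors are
    foreground, so an n-cube keeps n^3 - (n-2)^3 surface voxels."""
    assert len(extract_surface(_cube_mask(side))) == expected


def test_surface_of_empty_mask_raises():
    m = SegmentationMask(voxels=np.zeros((6, 6, 6), dtype=bool), spacing=(1, 1, 1),
                         role="liver")
    with pytest.raises(EmptyStructureError):
        extract_surface(m)


def test_surface_voxels_have_background_face_neighbor():
    mask = rasterize_sphere((16, 16, 16), 14.0, (32, 32, 32))
    surf = extract_surface(mask)
    vox = mask.voxels
    padded = np.pad(vox, 1)
    for i, j, k in surf.indices[::7]:
        nbrs = [
            padded[i + 1 + di, j + 1 + dj, k + 1 + dk]
            for di, dj, dk in ((1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0),
                               (0, 0, 1), (0, 0, -1))
        ]
        assert vox[i, j, k] and not all(nbrs)


def test_signed_distance_zero_on_surface_and_signs():
    mask = rasterize_sphere((12, 12, 12), 10.0, (24, 24, 24))
    sdm = signed_distance_map(mask)
    surf = extract_surface(mask).mask
    assert np.all(sdm.values[surf] == 0.0)
    assert np.all(sdm.values[mask.voxels] >= 0.0)
    assert np.all(sdm.values[~mask.voxels] < 0.0)


def test_signed_distance_straight_line_outside():
    """Three voxels straight out of a flat face is exactly -3 mm on a 1 mm grid."""
    mask = _cube_mask(5, pad=5, role="ablation")
    sdm = signed_distance_map(mask)
    # cube occupies [5,10); straight outside along +x from surface voxel (9,7,7)
    assert sdm.values[12, 7, 7] == -3.0


def test_signed_distance_anisotropic_spacing():
    mask = _cube_mask(3, pad=3, spacing=(1.0, 1.0, 2.5), role="ablation")
    sdm = signed_distance_map(mask)
    # one voxel step along the coarse axis from surface voxel (4,4,5)
    assert sdm.values[4, 4, 6] == -2.5


def test_identity_margins_are_zero():
    dist = compute_margins(cube_case())
    assert np.all(dist.margins == 0.0)


def test_identity_margins_interface_convention():
    dist = compute_margins(cube_case(), zero_set="interface")
    assert np.all(dist.margins == 1.0)


@pytest.mark.parametrize("spacing", [(1.0, 1.0, 1.0), (0.8, 0.8, 2.5)])
@pytest.mark.parametrize("zero_set", ["surface", "interface"])
def test_margins_match_brute_force_oracle(spacing, zero_set):
    for seed in (0, 1, 2):
        case = make_random_blob_case(seed=seed, max_extent=24, spacing=spacing)
        got = compute_margins(case, zero_set=zero_set).margins
        want = brute_force_margins(case, zero_set=zero_set)
        assert_margins_equal(got, want)


def test_sign_matches_ablation_membership():
    case = make_random_blob_case(seed=5, max_extent=24)
    dist = compute_margins(case)
    inside = case.ablation.voxels[tuple(dist.included.indices.T)]
    assert np.all((dist.margins < 0) == ~inside)


def test_mirror_symmetry_of_margin_multiset():
    case = make_random_blob_case(seed=9, max_extent=24)
    base = np.sort(compute_margins(case).margins)
    for axis in range(3):
        def flip(mask):
            return SegmentationMask(
                voxels=np.flip(mask.voxels, axis=axis).copy(),
                spacing=mask.spacing,
                role=mask.role,
            )

        mirrored = AblationCase(
            tumor=flip(case.tumor), ablation=flip(case.ablation), liver=None,
            case_id="mirror",
        )
        assert np.array_equal(np.sort(compute_margins(mirrored).margins), base)


def test_spacing_covariance_exact_for_factor_two():
    case = make_random_blob_case(seed=13, max_extent=24)

    def scaled(mask):
        return SegmentationMask(
            voxels=mask.voxels, spacing=tuple(2.0 * s for s in mask.spacing),
            role=mask.role,
        )

    doubled = AblationCase(
        tumor=scaled(case.tumor), ablation=scaled(case.ablation), liver=None,
        case_id="x2",
    )
    m1 = compute_margins(case).margins
    m2 = compute_margins(doubled).margins
    assert np.array_equal(2.0 * m1, m2)


def test_exclusion_threshold_zero_excludes_nothing(t22_case):
    surf = extract_surface(t22_case.tumor)
    included, excluded = exclude_subcapsular(surf, t22_case.liver, threshold=0.0)
    assert len(excluded) == 0
    assert len(included) == len(surf)


def test_exclusion_monotone_in_threshold(t22_case):
    surf = extract_surface(t22_case.tumor)
    sizes = []
    prev = None
    for thr in (0.0, 2.0, 4.0, 5.0, 6.0):
        _, excluded = exclude_subcapsular(surf, t22_case.liver, threshold=thr)
        rows = {tuple(r) for r in excluded}
        if prev is not None:
            assert prev <= rows
        prev = rows
        sizes.append(len(rows))
    assert sizes[0] == 0 and sizes == sorted(sizes)


def test_exclusion_far_tumor_excludes_nothing():
    """Tumor sphere >= 12 mm from a planar liver boundary: nothing within 5 mm."""
    shape = (48, 48, 48)
    tumor = rasterize_sphere((20.0, 24.0, 24.0), 10.0, shape)
    liver = rasterize_half_space(0, 37.0, shape)  # plane 12 mm past tumor surface
    surf = extract_surface(tumor)
    _, excluded = exclude_subcapsular(surf, liver, threshold=5.0)
    assert len(excluded) == 0


def test_exclusion_matches_planar_brute_force():
    case = make_subcapsular_planar_case(gap_mm=0.0)
    surf = extract_surface(case.tumor)
    included, excluded = exclude_subcapsular(surf, case.liver, threshold=5.0)
    want = brute_force_excluded(case, threshold=5.0)
    got = np.zeros(len(surf), dtype=bool)
    rows = {tuple(r) for r in excluded}
    for n, idx in enumerate(surf.indices):
        got[n] = tuple(idx) in rows
    assert np.array_equal(got, want)
    assert 0 < len(excluded) < len(surf)


def test_all_excluded_error_for_tiny_subcapsular_tumor():
    """A tumor entirely within 5 mm of the capsule yields no distances."""
    shape = (32, 32, 32)
    tumor = rasterize_sphere((16.0, 16.0, 16.0), 4.0, shape)
    ablation = rasterize_sphere((16.0, 16.0, 16.0), 8.0, shape)
    liver = rasterize_half_space(0, 18.5, shape)
    case = AblationCase(tumor=tumor, ablation=ablation, liver=liver, case_id="tiny")
    with pytest.raises(AllExcludedError, match="subcapsular"):
        compute_margins(case, use_exclusion=True)


def test_coverage_completeness(t22_case):
    n_surface = len(extract_surface(t22_case.tumor))
    dist = compute_margins(t22_case, use_exclusion=True)
    assert dist.n_included + dist.n_excluded == n_surface
    included_rows = {tuple(r) for r in dist.included.indices}
    excluded_rows = {tuple(r) for r in dist.excluded}
    assert not included_rows & excluded_rows


def test_missing_liver_error(t16_case):
    with pytest.raises(MissingLiverError):
        compute_margins(t16_case, use_exclusion=True)
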