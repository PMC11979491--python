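"""Grid geometry: partition invariants, point assignment, voxelization."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from braingrid import (
    GridSpec,
    GridSpecError,
    OutsideGridError,
    assign_point,
    build_grid,
    cell_label,
    parse_label,
    voxelize_mask,
)
from braingrid.grid import CELL_COUNT, cell_code


# --- spec validation ------------------------------------------------------


@pytest.mark.parametrize(
    "kwargs, match",
    [
        (dict(mediolateral_planes=(36.0, 0.0, -36.0)), "mediolateral"),
        (dict(mediolateral_planes=(-36.0, 5.0, 36.0)), "midline"),
        (dict(anteroposterior_planes=(-48.0, 12.0)), "anteroposterior"),
        (dict(dorsoventral_planes=(48.0, 12.0, 100.0)), "dorsoventral"),
    ],
)
def test_invalid_spec_names_offending_axis(kwargs, match):
    base = dict(
        mediolateral_planes=(-36.0, 0.0, 36.0),
        anteroposterior_planes=(12.0, -48.0),
        dorsoventral_planes=(48.0, 12.0, -24.0),
    )
    base.update(kwargs)
    with pytest.raises(GridSpecError, match=match):
        GridSpec(**base)


def test_default_grid_has_48_cells(grid):
    assert len(grid.cells) == 48
    assert sorted(grid.labels) == sorted(
        cell_label(a, c, s) for a in range(1, 5) for c in range(1, 4) for s in range(1, 5)
    )


def test_tiling_conserves_bounding_box_volume(grid, spec):
    box_ml = np.prod([hi - lo for lo, hi in spec.bounding_box]) / 1000.0
    assert sum(c.volume_ml for c in grid.cells) == pytest.approx(box_ml)


def test_unequal_spec_still_tiles():
    spec = GridSpec(
        (-50.0, 0.0, 20.0), (30.0, -60.0), (60.0, 30.0, -10.0),
    )
    grid = build_grid(spec)
    box_ml = np.prod([hi - lo for lo, hi in spec.bounding_box]) / 1000.0
    assert sum(c.volume_ml for c in grid.cells) == pytest.approx(box_ml)


def test_axis_independence_of_plane_changes(spec):
    other = GridSpec(
        spec.mediolateral_planes,
        (20.0, -20.0),
        spec.dorsoventral_planes,
        spec.bounding_box,
    )
    g1, g2 = build_grid(spec), build_grid(other)
    for c1, c2 in zip(g1.cells, g2.cells):
        assert c1.box[0] == c2.box[0]  # A extents unchanged
        assert c1.box[2] == c2.box[2]  # S extents unchanged
    assert any(c1.box[1] != c2.box[1] for c1, c2 in zip(g1.cells, g2.cells))


# --- label round trip -----------------------------------------------------


@pytest.mark.parametrize("a,c,s", [(a, c, s) for a in (1, 4) for c in (1, 3) for s in (1, 4)])
def test_label_round_trips(a, c, s):
    assert parse_label(cell_label(a, c, s)) == (a, c, s)


@pytest.mark.parametrize("bad", ["A5C1S1", "A1C4S1", "a1c1s1", "A1C1", "A1C1S5"])
def test_malformed_labels_rejected(bad):
    with pytest.raises(ValueError):
        parse_label(bad)


# --- point assignment -----------------------------------------------------


def test_far_left_anterior_superior_is_A4C1S1(grid):
    assert assign_point(grid, (-60.0, 70.0, 82.0)) == "A4C1S1"


def test_mirror_across_midline_swaps_hemisphere_only(grid):
    left = assign_point(grid, (-60.0, 70.0, 82.0))
    right = assign_point(grid, (60.0, 70.0, 82.0))
    assert left == "A4C1S1" and right == "A1C1S1"


def test_exact_midline_goes_left_medial(grid):
    assert assign_point(grid, (0.0, 0.0, 0.0)).startswith("A3")


def test_point_outside_box_raises(grid):
    with pytest.raises(OutsideGridError):
        assign_point(grid, (500.0, 0.0, 0.0))


@settings(max_examples=200, deadline=None, derandomize=True)
@given(
    x=st.floats(-71.9, 71.9),
    y=st.floats(-107.9, 71.9),
    z=st.floats(-59.9, 83.9),
)
def test_every_point_maps_to_exactly_one_cell_in_correct_hemisphere(grid, x, y, z):
    label = assign_point(grid, (x, y, z))
    a, _, _ = parse_label(label)
    if x > 0:
        assert a in (1, 2)
    elif x < 0:
        assert a in (3, 4)
    # containment: the point lies inside the assigned half-open box
    box = grid.cell(label).box
    for coord, (lo, hi) in zip((x, y, z), box):
        assert lo <= coord <= hi


# --- voxelization ---------------------------------------------------------


def _identity_affine(spacing, origin):
    aff = np.eye(4)
    aff[:3, :3] *= spacing
    aff[:3, 3] = origin
    return aff


def test_empty_mask_gives_all_zero(grid):
    aff = _identity_affine(4.0, (-70.0, -106.0, -58.0))
    vols = voxelize_mask(grid, np.zeros((8, 8, 8), np.int8), aff)
    assert vols.shape == (48,)
    assert np.all(vols == 0)


def test_mask_inside_one_cell_hits_exactly_that_cell(grid):
    aff = _identity_affine(2.0, (50.0, 50.0, 60.0))  # strictly inside A1C1S1
    data = np.zeros((4, 4, 4), np.int8)
    data[1:3, 1:3, 1:3] = 1
    vols = voxelize_mask(grid, data, aff)
    assert np.count_nonzero(vols) == 1
    assert vols[grid.cell("A1C1S1").code - 1] == pytest.approx(8 * 8 / 1000.0)


def test_straddling_mask_matches_brute_force_oracle(grid, brute_force_voxelize):
    # a slab crossing the x = 36 lateral plane inside the right hemisphere
    aff = _identity_affine(3.0, (25.0, 40.0, 50.0))
    data = np.zeros((8, 4, 4), np.int8)
    data[:, 1:3, 1:3] = 1
    vols = voxelize_mask(grid, data, aff)
    oracle = brute_force_voxelize(grid, data, aff)
    np.testing.assert_allclose(vols, oracle)
    assert np.count_nonzero(vols) == 2
    assert vols.sum() == pytest.approx(data.sum() * 27 / 1000.0)


def test_random_blob_matches_brute_force_oracle(grid, brute_force_voxelize):
    rng = np.random.default_rng(3)
    data = (rng.random((12, 12, 12)) < 0.3).astype(np.int8)
    aff = _identity_affine(5.0, (-40.0, -50.0, -20.0))
    np.testing.assert_allclose(
        voxelize_mask(grid, data, aff), brute_force_voxelize(grid, data, aff)
    )


def test_mirror_symmetry_of_voxelization(grid):
    # voxel centres at +-2, +-6, ... avoid all planes; reflect about x = 0
    aff = _identity_affine(4.0, (2.0, 10.0, 10.0))
    data = np.zeros((6, 4, 4), np.int8)
    data[::2, 1:3, 1:3] = 1
    vols = voxelize_mask(grid, data, aff)
    aff_m = _identity_affine(4.0, (2.0, 10.0, 10.0))
    aff_m[0, 0] = -4.0
    aff_m[0, 3] = -2.0
    vols_m = voxelize_mask(grid, data, aff_m)
    swapped = vols_m.reshape(4, 12)[::-1].reshape(48)  # A1<->A4, A2<->A3
    np.testing.assert_allclose(vols, swapped)


def test_non_binary_mask_rejected(grid):
    aff = _identity_affine(4.0, (0.0, 0.0, 0.0))
    with pytest.raises(ValueError, match="binary"):
        voxelize_mask(grid, np.full((4, 4, 4), 2.0), aff)


def test_missing_affine_rejected(grid):
    with pytest.raises(ValueError, match="affine"):
        voxelize_mask(grid, np.zeros((4, 4, 4)), None)


def test_label_volume_round_trips_through_assignment(grid, small_ref):
    labels = grid.label_volume(small_ref.shape, small_ref.affine)
    assert labels.min() >= 1 and labels.max() == 48  # lattice covers the box
    xyz = small_ref.world_coordinates()
    codes = grid.assign_points(xyz, strict=False).reshape(small_ref.shape)
    np.testing.assert_array_equal(labels, codes)
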