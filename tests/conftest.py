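"""Shared fixtures: default grid, small lattices, synthetic cohorts, and a
93-patient cohort reconstructed from published marginal counts."""

from __future__ import annotations

import numpy as np
import pytest

from braingrid import (
    Cohort,
    GridSpec,
    PatientRecord,
    ReferenceGeometry,
    SimulationConfig,
    build_grid,
    generate_cohort,
)


@pytest.fixture(scope="session")
def brute_force_voxelize():
    """Independent per-voxel assignment loop — the voxelization oracle."""
    import nibabel as nib

    from braingrid import assign_point, parse_label
    from braingrid.grid import CELL_COUNT, cell_code

    def oracle(grid, data, affine):
        vox_ml = abs(np.linalg.det(affine[:3, :3])) / 1000.0
        volumes = np.zeros(CELL_COUNT)
        for ijk in np.argwhere(data):
            xyz = nib.affines.apply_affine(affine, ijk)
            a, c, s = parse_label(assign_point(grid, xyz))
            volumes[cell_code(a, c, s) - 1] += vox_ml
        return volumes

    return oracle


@pytest.fixture(scope="session")
def spec() -> GridSpec:
    return GridSpec.default()


@pytest.fixture(scope="session")
def grid(spec):
    return build_grid(spec)


@pytest.fixture(scope="session")
def small_ref(spec) -> ReferenceGeometry:
    """32-cubed lattice over the template box (fast, anisotropic voxels)."""
    return ReferenceGeometry.from_box_shape(spec.bounding_box, (32, 32, 32))


@pytest.fixture(scope="session")
def synthetic_20(small_ref):
    """20-patient synthetic cohort on the 32-cubed lattice."""
    return generate_cohort(
        SimulationConfig(n_patients=20, seed=11, reference_shape=(32, 32, 32))
    )


@pytest.fixture(scope="session")
def fixture_tree(tmp_path_factory):
    from braingrid import make_fixture_suite

    out = tmp_path_factory.mktemp("fixtures")
    return make_fixture_suite(out / "suite")


def _stratum(n, n_male, n_a2, n_a3, n_o2, n_o3, borders, seizure, start):
    """Build one seizure stratum consistent with its marginal counts."""
    assert n_male <= n and n_a2 + n_a3 + n_o2 + n_o3 == n and len(borders) == n
    records = []
    diag = (
        [("astrocytoma", 2)] * n_a2
        + [("astrocytoma", 3)] * n_a3
        + [("oligodendroglioma", 2)] * n_o2
        + [("oligodendroglioma", 3)] * n_o3
    )
    for i in range(n):
        d, g = diag[i]
        records.append(
            PatientRecord(
                id=f"t{start + i:03d}",
                diagnosis=d,
                grade=g,
                sex="male" if i < n_male else "female",
                age_years=42.0,
                volume_ml=62.0,
                border=borders[i],
                seizure=seizure,
            )
        )
    return records


@pytest.fixture(scope="session")
def marginal_cohort() -> Cohort:
    """93 patients reproducing the published characteristics-table marginals:
    70 with seizures (49 male, 21 female of 58/35), diagnosis-grade counts
    34/16/31/12 with 27/13/21/9 seizures, borders 54 diffuse (42 with
    seizures), 29 sharp (28), 10 unrecorded."""
    with_seizure = _stratum(
        70, 49, 27, 13, 21, 9,
        ["diffuse"] * 42 + ["sharp"] * 28, True, 0,
    )
    without = _stratum(
        23, 9, 7, 3, 10, 3,
        ["diffuse"] * 12 + ["sharp"] * 1 + [None] * 10, False, 100,
    )
    return Cohort(with_seizure + without, provenance="published marginals")
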