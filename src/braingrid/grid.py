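"""Brain-grid partition of template space.

The brain-grid divides a template-space (MNI, RAS mm) bounding box into 48
large sublobar cells by two coronal planes, three axial... strictly: three
mediolateral (sagittal) planes, two anteroposterior (coronal) planes and
three dorsoventral (axial) planes.  Cells are labelled ``AxCySz``:

* **A** (1-4) runs right → left along x.  A1/A2 are the right-hemisphere
  lateral/medial bands (x > 0), A3/A4 the left-hemisphere medial/lateral
  bands (x < 0).
* **C** (1-3) runs anterior → posterior along y; C1 is the most anterior.
* **S** (1-4) runs superior → inferior along z; S1 is the most superior.

Each cell is an axis-aligned box.  Assignment is half-open along the label
direction: a cell owns its first edge (the higher-coordinate one on every
axis, since all three label indices increase as the coordinate decreases)
and excludes the other, so every interior point belongs to exactly one cell
and the exact midline x = 0 falls in the left-medial (A3) band.

All geometry is expressed in template millimetres through the volume affine,
never in raw voxel indices, so mixed-resolution inputs are handled uniformly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import nibabel as nib
import numpy as np

__all__ = [
    "GridSpec",
    "GridCell",
    "BrainGrid",
    "GridSpecError",
    "OutsideGridError",
    "build_grid",
    "cell_label",
    "parse_label",
    "assign_point",
    "voxelize_mask",
    "CELL_COUNT",
]

CELL_COUNT = 48

#: Default template-space bounding box (mm), a symmetric box enclosing the
#: MNI brain: x right, y anterior, z superior.
DEFAULT_BOUNDING_BOX = ((-72.0, 72.0), (-108.0, 72.0), (-60.0, 84.0))


class GridSpecError(ValueError):
    """Invalid grid specification (names the offending axis)."""


class OutsideGridError(ValueError):
    """A queried point lies outside the grid bounding box."""


def cell_label(a: int, c: int, s: int) -> str:
    """Format the ``AxCySz`` label for the given band indices."""
    if not (1 <= a <= 4 and 1 <= c <= 3 and 1 <= s <= 4):
        raise ValueError(f"band indices out of range: A{a}C{c}S{s}")
    return f"A{a}C{c}S{s}"


def parse_label(label: str) -> tuple[int, int, int]:
    """Invert :func:`cell_label`; raises ``ValueError`` on malformed input."""
    import re

    m = re.fullmatch(r"A([1-4])C([1-3])S([1-4])", label)
    if m is None:
        raise ValueError(f"not a grid cell label: {label!r}")
    return int(m.group(1)), int(m.group(2)), int(m.group(3))


def cell_code(a: int, c: int, s: int) -> int:
    """Integer code 1..48 for a cell, ordered A-major then C then S."""
    return (a - 1) * 12 + (c - 1) * 4 + s


@dataclass(frozen=True)
class GridSpec:
    """Plane coordinates (template mm) defining the 48-cell partition.

    ``mediolateral_planes`` are ascending x coordinates with the middle one
    fixed at the midline (x = 0); ``anteroposterior_planes`` are descending y
    coordinates (anterior first); ``dorsoventral_planes`` are descending z
    coordinates (superior first).  All planes must lie strictly inside
    ``bounding_box``.
    """

    mediolateral_planes: tuple[float, float, float]
    anteroposterior_planes: tuple[float, float]
    dorsoventral_planes: tuple[float, float, float]
    bounding_box: tuple[tuple[float, float], tuple[float, float], tuple[float, float]] = (
        DEFAULT_BOUNDING_BOX
    )
    template: str = "MNI152"

    def __post_init__(self) -> None:
        for (lo, hi), name in zip(self.bounding_box, "xyz"):
            if not lo < hi:
                raise GridSpecError(f"degenerate bounding box on axis {name}")
        ml = self.mediolateral_planes
        if list(ml) != sorted(ml) or len(set(ml)) != 3:
            raise GridSpecError("mediolateral planes must be strictly ascending")
        if ml[1] != 0.0:
            raise GridSpecError("middle mediolateral plane must sit at the midline x=0")
        ap = self.anteroposterior_planes
        if list(ap) != sorted(ap, reverse=True) or len(set(ap)) != 2:
            raise GridSpecError("anteroposterior planes must be strictly descending")
        dv = self.dorsoventral_planes
        if list(dv) != sorted(dv, reverse=True) or len(set(dv)) != 3:
            raise GridSpecError("dorsoventral planes must be strictly descending")
        for planes, (lo, hi), name in (
            (ml, self.bounding_box[0], "mediolateral"),
            (ap, self.bounding_box[1], "anteroposterior"),
            (dv, self.bounding_box[2], "dorsoventral"),
        ):
            for p in planes:
                if not lo < p < hi:
                    raise GridSpecError(
                        f"{name} plane {p} mm outside bounding box ({lo}, {hi})"
                    )

    @classmethod
    def default(cls, bounding_box=DEFAULT_BOUNDING_BOX, template: str = "MNI152") -> "GridSpec":
        """Fractional-division default: symmetric lateral planes at half the
        hemispheric width, equal anteroposterior thirds and dorsoventral
        quarters.  A stand-in for anatomically landmarked planes, which may
        be supplied explicitly instead."""
        (x0, x1), (y0, y1), (z0, z1) = bounding_box
        ml = (x0 / 2.0, 0.0, x1 / 2.0)
        ap = (y0 + 2.0 * (y1 - y0) / 3.0, y0 + (y1 - y0) / 3.0)
        dv = (
            z0 + 3.0 * (z1 - z0) / 4.0,
            z0 + 2.0 * (z1 - z0) / 4.0,
            z0 + (z1 - z0) / 4.0,
        )
        return cls(ml, ap, dv, bounding_box, template)


@dataclass(frozen=True)
class GridCell:
    label: str
    a: int
    c: int
    s: int
    code: int
    box: tuple[tuple[float, float], tuple[float, float], tuple[float, float]]

    @property
    def volume_ml(self) -> float:
        v = 1.0
        for lo, hi in self.box:
            v *= hi - lo
        return v / 1000.0

    @property
    def centre(self) -> tuple[float, float, float]:
        return tuple((lo + hi) / 2.0 for lo, hi in self.box)  # type: ignore[return-value]


def _band_edges(planes: Sequence[float], lo: float, hi: float, descending: bool):
    """Edges per band index, ordered by increasing label index."""
    if descending:
        return [hi] + list(planes) + [lo]
    return [lo] + list(planes) + [hi]


@dataclass(frozen=True)
class BrainGrid:
    """The realised 48-cell partition; build with :func:`build_grid`."""

    spec: GridSpec
    cells: tuple[GridCell, ...]

    def __post_init__(self) -> None:
        if len(self.cells) != CELL_COUNT:
            raise ValueError("a brain grid has exactly 48 cells")

    @property
    def labels(self) -> list[str]:
        return [c.label for c in self.cells]

    def cell(self, label: str) -> GridCell:
        a, c, s = parse_label(label)
        return self.cells[cell_code(a, c, s) - 1]

    # --- point assignment -------------------------------------------------

    def _band_indices(self, xyz: np.ndarray) -> np.ndarray:
        """Vectorised band indices for an (n, 3) array of mm coordinates.

        Returns (n, 3) integer indices (1-based: A, C, S).  Points outside
        the bounding box get index 0 on the offending axis.
        """
        xyz = np.asarray(xyz, dtype=float)
        out = np.zeros(xyz.shape, dtype=np.int64)
        spec = self.spec
        axis_planes = (
            spec.mediolateral_planes,
            spec.anteroposterior_planes,
            spec.dorsoventral_planes,
        )
        for ax in range(3):
            lo, hi = spec.bounding_box[ax]
            coord = xyz[:, ax]
            planes = np.asarray(axis_planes[ax], dtype=float)
            # Label index increases as the coordinate decreases on every axis;
            # a plane belongs to the band below it (higher index).
            idx = (planes[None, :] >= coord[:, None]).sum(axis=1) + 1
            inside = (coord >= lo) & (coord <= hi)
            out[:, ax] = np.where(inside, idx, 0)
        return out

    def assign_points(self, xyz: np.ndarray, *, strict: bool = True) -> np.ndarray:
        """Cell codes (1..48) for an (n, 3) array of template-mm points.

        Out-of-box points raise :class:`OutsideGridError` when ``strict``,
        otherwise receive code 0.
        """
        bands = self._band_indices(np.atleast_2d(xyz))
        outside = (bands == 0).any(axis=1)
        if strict and outside.any():
            i = int(np.argmax(outside))
            raise OutsideGridError(
                f"point {np.atleast_2d(xyz)[i]} lies outside the grid bounding box"
            )
        codes = (bands[:, 0] - 1) * 12 + (bands[:, 1] - 1) * 4 + bands[:, 2]
        codes[outside] = 0
        return codes

    # --- label volume export ----------------------------------------------

    def label_volume(self, shape: tuple[int, int, int], affine: np.ndarray) -> np.ndarray:
        """Integer label volume (codes 1..48, 0 outside the box) on an
        arbitrary reference geometry."""
        ii, jj, kk = np.meshgrid(*(np.arange(n) for n in shape), indexing="ij")
        ijk = np.column_stack([ii.ravel(), jj.ravel(), kk.ravel()])
        xyz = nib.affines.apply_affine(affine, ijk)
        codes = self.assign_points(xyz, strict=False)
        return codes.reshape(shape).astype(np.int16)

    def to_nifti(self, shape: tuple[int, int, int], affine: np.ndarray) -> nib.Nifti1Image:
        return nib.Nifti1Image(self.label_volume(shape, affine), affine)


def build_grid(spec: GridSpec) -> BrainGrid:
    """Construct the 48-cell grid from plane coordinates.

    The cell boxes tile the bounding box exactly (no overlap, no gap); box
    bounds are stored ascending per axis regardless of label direction.
    """
    (x0, x1), (y0, y1), (z0, z1) = spec.bounding_box
    # Edges ordered by increasing label index (i.e. decreasing coordinate).
    xe = _band_edges(spec.mediolateral_planes[::-1], x0, x1, descending=True)
    ye = _band_edges(spec.anteroposterior_planes, y0, y1, descending=True)
    ze = _band_edges(spec.dorsoventral_planes, z0, z1, descending=True)
    cells = []
    for a in range(1, 5):
        for c in range(1, 4):
            for s in range(1, 5):
                box = (
                    (xe[a], xe[a - 1]),
                    (ye[c], ye[c - 1]),
                    (ze[s], ze[s - 1]),
                )
                cells.append(
                    GridCell(cell_label(a, c, s), a, c, s, cell_code(a, c, s), box)
                )
    return BrainGrid(spec, tuple(cells))


def assign_point(grid: BrainGrid, location: Iterable[float]) -> str:
    """Label of the unique cell containing a template-mm point."""
    code = int(grid.assign_points(np.asarray(list(location), float)[None, :])[0])
    return grid.cells[code - 1].label


def _check_binary(data: np.ndarray) -> np.ndarray:
    arr = np.asarray(data)
    if arr.ndim != 3:
        raise ValueError(f"mask must be a 3D volume, got shape {arr.shape}")
    vals = np.unique(arr)
    if not np.all(np.isin(vals, (0, 1))):
        raise ValueError("mask volume is not binary (values other than 0/1 found)")
    return arr.astype(bool)


def voxelize_mask(grid: BrainGrid, data: np.ndarray, affine: np.ndarray) -> np.ndarray:
    """Per-cell overlap volume (mL) of a binary mask.

    Every nonzero voxel is assigned to the single cell containing its centre
    (half-open rule), so the 48 volumes sum exactly to the mask volume for
    masks whose voxel centres lie inside the bounding box; centres outside
    the box are dropped.
    """
    if affine is None:
        raise ValueError("mask affine is required to map voxels to template mm")
    mask = _check_binary(data)
    affine = np.asarray(affine, dtype=float)
    vox_ml = float(abs(np.linalg.det(affine[:3, :3]))) / 1000.0
    volumes = np.zeros(CELL_COUNT, dtype=float)
    idx = np.argwhere(mask)
    if idx.size == 0:
        return volumes
    xyz = nib.affines.apply_affine(affine, idx)
    codes = grid.assign_points(xyz, strict=False)
    counts = np.bincount(codes[codes > 0], minlength=CELL_COUNT + 1)[1:]
    return counts.astype(float) * vox_ml
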