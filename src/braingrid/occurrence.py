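"""Group-normalised tumour occurrence-weighted maps.

An occurrence map for a patient group holds, at every voxel of a reference
geometry, the fraction of the group's tumour masks that cover the voxel —
the voxelwise mean of the binary masks, normalised by group size N.  Values
live in [0, 1].  Masks on a different geometry are resampled to the
reference by nearest neighbour (binary masks stay binary; no smoothing).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import nibabel as nib
import numpy as np
import pandas as pd
from scipy import ndimage

from .grid import BrainGrid, _check_binary
from .involvement import InvolvementMatrix

__all__ = [
    "ReferenceGeometry",
    "OccurrenceMap",
    "group_occurrence",
    "cell_frequency_table",
    "peak_occurrence",
]


@dataclass(frozen=True)
class ReferenceGeometry:
    """A voxel lattice in template space: shape plus RAS affine."""

    shape: tuple[int, int, int]
    affine: np.ndarray

    @classmethod
    def from_box(cls, bounding_box, spacing: float = 2.0) -> "ReferenceGeometry":
        """Isotropic lattice of voxel *centres* spanning a template-mm box.

        The default 2 mm spacing keeps maps fast while preserving structure;
        1 mm is a config choice away.
        """
        shape = []
        origin = []
        for lo, hi in bounding_box:
            n = int(np.floor((hi - lo) / spacing))
            shape.append(n)
            origin.append(lo + spacing / 2.0)
        affine = np.eye(4)
        affine[:3, :3] *= spacing
        affine[:3, 3] = origin
        return cls(tuple(shape), affine)

    @classmethod
    def from_box_shape(cls, bounding_box, shape) -> "ReferenceGeometry":
        """Lattice with a fixed shape (possibly anisotropic spacing)."""
        spacing = []
        origin = []
        for (lo, hi), n in zip(bounding_box, shape):
            s = (hi - lo) / n
            spacing.append(s)
            origin.append(lo + s / 2.0)
        affine = np.eye(4)
        affine[:3, :3] = np.diag(spacing)
        affine[:3, 3] = origin
        return cls(tuple(int(n) for n in shape), affine)

    def voxel_volume_ml(self) -> float:
        return float(abs(np.linalg.det(np.asarray(self.affine)[:3, :3]))) / 1000.0

    def world_coordinates(self) -> np.ndarray:
        """(n, 3) template-mm coordinates of all voxel centres."""
        ii, jj, kk = np.meshgrid(*(np.arange(n) for n in self.shape), indexing="ij")
        ijk = np.column_stack([ii.ravel(), jj.ravel(), kk.ravel()])
        return nib.affines.apply_affine(np.asarray(self.affine, float), ijk)

    def matches(self, shape, affine) -> bool:
        return tuple(shape) == self.shape and np.allclose(affine, self.affine)


def resample_nearest(data: np.ndarray, affine: np.ndarray, reference: ReferenceGeometry) -> np.ndarray:
    """Nearest-neighbour resampling of a volume onto the reference lattice."""
    src_affine = np.asarray(affine, float)
    mapping = np.linalg.inv(src_affine) @ np.asarray(reference.affine, float)
    ii, jj, kk = np.meshgrid(*(np.arange(n) for n in reference.shape), indexing="ij")
    ijk = np.stack([ii, jj, kk], axis=0).reshape(3, -1)
    src_ijk = mapping[:3, :3] @ ijk + mapping[:3, 3:4]
    out = ndimage.map_coordinates(
        np.asarray(data, float), src_ijk, order=0, mode="constant", cval=0.0
    )
    return out.reshape(reference.shape)


@dataclass
class OccurrenceMap:
    data: np.ndarray
    reference: ReferenceGeometry
    group: str
    n: int

    def __post_init__(self) -> None:
        d = np.asarray(self.data, float)
        if d.min() < 0 or d.max() > 1 + 1e-12:
            raise ValueError("occurrence values must lie in [0, 1]")

    def to_nifti(self) -> nib.Nifti1Image:
        return nib.Nifti1Image(np.asarray(self.data, np.float32), self.reference.affine)


def group_occurrence(
    masks: Sequence[tuple[np.ndarray, np.ndarray]],
    reference: ReferenceGeometry,
    group: str = "all",
) -> OccurrenceMap:
    """Voxelwise mean of a group's binary masks on the reference geometry.

    ``masks`` is a sequence of (data, affine) pairs; an empty group has an
    undefined normalisation and is an error.
    """
    if len(masks) == 0:
        raise ValueError(f"occurrence map for group {group!r}: empty group")
    acc = np.zeros(reference.shape, dtype=float)
    for data, affine in masks:
        binary = _check_binary(data)
        if reference.matches(binary.shape, affine):
            acc += binary
        else:
            acc += resample_nearest(binary, affine, reference)
    return OccurrenceMap(acc / len(masks), reference, group, len(masks))


def cell_frequency_table(
    grid: BrainGrid,
    matrix: InvolvementMatrix,
    outcome: pd.Series,
) -> pd.DataFrame:
    """Per-cell involvement counts and percentages by outcome group.

    ``outcome`` is a boolean Series indexed by patient id (seizure yes/no);
    patients with missing outcome are excluded listwise.  Returns one row
    per (cell, group) with ``involved``, ``group_n`` and ``pct``.
    """
    outcome = outcome.reindex(matrix.frame.index)
    keep = outcome.notna()
    frame = matrix.frame.loc[keep]
    outcome = outcome.loc[keep].astype(bool)
    rows = []
    for group, flag in (("seizure", True), ("no_seizure", False)):
        sub = frame.loc[outcome == flag]
        counts = sub.sum(axis=0)
        for label in frame.columns:
            c = int(counts[label])
            rows.append(
                {
                    "cell": label,
                    "group": group,
                    "involved": c,
                    "group_n": len(sub),
                    "pct": 100.0 * c / len(sub) if len(sub) else np.nan,
                }
            )
    return pd.DataFrame(rows)


def peak_occurrence(occ: OccurrenceMap, grid: Optional[BrainGrid] = None):
    """Maximum occurrence value and, when a grid is given, the label of the
    cell containing the arg-max voxel (ties broken by lowest cell code)."""
    data = np.asarray(occ.data, float)
    peak = float(data.max())
    if grid is None:
        return peak, None
    if peak == 0.0:
        return 0.0, None
    flat = np.flatnonzero(data == peak)
    idx = np.array(np.unravel_index(flat, data.shape)).T
    xyz = nib.affines.apply_affine(np.asarray(occ.reference.affine, float), idx)
    codes = grid.assign_points(xyz, strict=False)
    codes = codes[codes > 0]
    if codes.size == 0:
        return peak, None
    return peak, grid.cells[int(codes.min()) - 1].label
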