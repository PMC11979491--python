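"""White-matter tract atlas overlap.

The atlas is a set of named binary masks in template space — by default the
eight major bundles used in sublobar glioma topography work: IFOF, CST, UF,
aSLF, pSLF, AF, FAT and Ci.  Tract masks are *inputs*; no tractography is
performed here.  A deterministic synthetic "toy atlas" of eight labelled
tubes with plausible courses is provided so the pipeline and its tests need
no external diffusion template.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Optional

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

from .grid import BrainGrid, _check_binary, voxelize_mask
from .occurrence import OccurrenceMap, ReferenceGeometry, resample_nearest

logger = logging.getLogger("braingrid")

__all__ = [
    "TRACT_NAMES",
    "TractAtlas",
    "load_atlas",
    "toy_atlas",
    "cell_tract_membership",
    "occurrence_tract_profile",
]

TRACT_NAMES = ("IFOF", "CST", "UF", "aSLF", "pSLF", "AF", "FAT", "Ci")


@dataclass
class TractAtlas:
    """Named binary tract volumes, each with its own affine."""

    tracts: dict[str, tuple[np.ndarray, np.ndarray]]
    provenance: str = ""

    def __post_init__(self) -> None:
        checked = {}
        for name, (data, affine) in self.tracts.items():
            binary = _check_binary(data)
            if not binary.any():
                logger.warning("tract %s has zero volume", name)
            checked[name] = (binary, np.asarray(affine, float))
        self.tracts = checked

    @property
    def names(self) -> list[str]:
        return list(self.tracts)

    def __len__(self) -> int:
        return len(self.tracts)


def load_atlas(paths: Mapping[str, Path] | Path, expected=TRACT_NAMES) -> TractAtlas:
    """Load per-tract NIfTI masks, from a name→path mapping or a YAML
    manifest file mapping tract names to (relative) paths."""
    if not isinstance(paths, Mapping):
        manifest = Path(paths)
        mapping = yaml.safe_load(manifest.read_text())
        paths = {name: manifest.parent / p for name, p in mapping.items()}
    missing = [name for name in expected if name not in paths]
    if missing:
        raise ValueError(f"missing tract(s) in atlas: {', '.join(missing)}")
    tracts = {}
    for name in expected:
        path = Path(paths[name])
        if not path.exists():
            raise FileNotFoundError(f"tract {name}: file not found: {path}")
        img = nib.load(str(path))
        tracts[name] = (np.asarray(img.dataobj), img.affine)
    atlas = TractAtlas(tracts, provenance=f"loaded {len(tracts)} tracts")
    for name, (data, affine) in atlas.tracts.items():
        vox_ml = abs(np.linalg.det(affine[:3, :3])) / 1000.0
        logger.info("tract %s: %.1f mL", name, data.sum() * vox_ml)
    return atlas


# Synthetic tube courses (template mm), loosely following each bundle's
# anatomy: (start, end, radius).  Left-hemisphere courses; deterministic.
_TOY_COURSES = {
    "IFOF": ((-30.0, 50.0, -5.0), (-30.0, -75.0, -5.0), 7.0),
    "CST": ((-25.0, -25.0, 70.0), (-10.0, -25.0, -45.0), 6.0),
    "UF": ((-35.0, 35.0, -15.0), (-40.0, 5.0, -30.0), 6.0),
    "aSLF": ((-45.0, 40.0, 25.0), (-45.0, -35.0, 40.0), 6.0),
    "pSLF": ((-45.0, -35.0, 40.0), (-50.0, -60.0, 10.0), 6.0),
    "AF": ((-48.0, 30.0, 10.0), (-52.0, -50.0, 0.0), 6.0),
    "FAT": ((-12.0, 40.0, 45.0), (-45.0, 15.0, 20.0), 5.5),
    "Ci": ((-8.0, 35.0, 25.0), (-8.0, -45.0, 30.0), 4.5),
}


def _tube(reference: ReferenceGeometry, start, end, radius: float) -> np.ndarray:
    """Rasterize a capsule (cylinder with spherical caps) on the lattice."""
    xyz = reference.world_coordinates()
    p0 = np.asarray(start, float)
    d = np.asarray(end, float) - p0
    length2 = float(d @ d)
    t = np.clip((xyz - p0) @ d / length2, 0.0, 1.0)
    nearest = p0[None, :] + t[:, None] * d[None, :]
    dist = np.linalg.norm(xyz - nearest, axis=1)
    return (dist <= radius).reshape(reference.shape).astype(np.int8)


def toy_atlas(reference: ReferenceGeometry, names=TRACT_NAMES) -> TractAtlas:
    """Deterministic 8-tube synthetic atlas on the given reference lattice."""
    tracts = {}
    for name in names:
        start, end, radius = _TOY_COURSES[name]
        tracts[name] = (_tube(reference, start, end, radius), reference.affine)
    return TractAtlas(tracts, provenance="synthetic toy atlas (8 capsules)")


def cell_tract_membership(
    grid: BrainGrid, atlas: TractAtlas, min_volume_ml: float = 0.0
) -> pd.DataFrame:
    """Cell × tract overlap volume (mL) and boolean membership.

    Membership is overlap > ``min_volume_ml``; it is monotone non-increasing
    in the threshold.
    """
    rows = []
    for name, (data, affine) in atlas.tracts.items():
        volumes = voxelize_mask(grid, data, affine)
        for cell, vol in zip(grid.cells, volumes):
            rows.append(
                {
                    "cell": cell.label,
                    "tract": name,
                    "overlap_ml": float(vol),
                    "member": bool(vol > min_volume_ml),
                }
            )
    return pd.DataFrame(rows)


def occurrence_tract_profile(occ: OccurrenceMap, atlas: TractAtlas) -> pd.DataFrame:
    """Per-tract occurrence summary: mean and max occurrence within the
    tract mask and the occupied fraction (share of tract voxels with any
    occurrence).  Tracts on a different lattice are resampled to the map's
    reference with a warning."""
    rows = []
    data = np.asarray(occ.data, float)
    for name, (tract, affine) in atlas.tracts.items():
        if occ.reference.matches(tract.shape, affine):
            mask = tract.astype(bool)
        else:
            logger.warning("tract %s resampled onto the occurrence geometry", name)
            mask = resample_nearest(tract, affine, occ.reference).astype(bool)
        n_vox = int(mask.sum())
        if n_vox == 0:
            rows.append(
                {"tract": name, "mean": 0.0, "max": 0.0, "occupied_fraction": 0.0,
                 "tract_voxels": 0}
            )
            continue
        vals = data[mask]
        rows.append(
            {
                "tract": name,
                "mean": float(vals.mean()),
                "max": float(vals.max()),
                "occupied_fraction": float((vals > 0).mean()),
                "tract_voxels": n_vox,
            }
        )
    return pd.DataFrame(rows).set_index("tract")
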