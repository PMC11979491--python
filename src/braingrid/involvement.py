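"""Patients × 48-cell binary involvement matrix.

A grid cell is *involved* by a tumour when the mask-cell overlap volume
exceeds ``threshold_ml``.  The default threshold is 0 mL — any overlap
counts — the most permissive reading; the threshold is exposed as a
sensitivity knob.  The per-patient row sum is the invasiveness count
(number of cells involved).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Optional

import nibabel as nib
import numpy as np
import pandas as pd

from .grid import CELL_COUNT, BrainGrid, voxelize_mask

logger = logging.getLogger("braingrid")

__all__ = ["InvolvementMatrix", "involvement_vector", "build_matrix"]


@dataclass
class InvolvementMatrix:
    """Binary involvement with its provenance.

    ``frame`` is a patients × 48 DataFrame of 0/1 with patient ids as the
    index and cell labels as columns, in canonical A-major order.
    """

    frame: pd.DataFrame
    threshold_ml: float
    failures: dict[str, str]

    def __post_init__(self) -> None:
        vals = self.frame.to_numpy()
        if not np.all(np.isin(vals, (0, 1))):
            raise ValueError("involvement entries must be 0/1")
        if self.frame.shape[1] != CELL_COUNT:
            raise ValueError("involvement matrix must have 48 cell columns")

    @property
    def patient_counts(self) -> pd.Series:
        """Cells involved per patient (invasiveness count)."""
        return self.frame.sum(axis=1)

    @property
    def cell_counts(self) -> pd.Series:
        """Involved patients per cell."""
        return self.frame.sum(axis=0)

    def write(self, csv_path, sidecar: Optional[dict] = None) -> Path:
        csv_path = Path(csv_path)
        self.frame.to_csv(csv_path)
        meta = {"threshold_ml": self.threshold_ml, "failures": self.failures}
        if sidecar:
            meta.update(sidecar)
        csv_path.with_suffix(".json").write_text(json.dumps(meta, indent=2))
        return csv_path


def involvement_vector(
    grid: BrainGrid,
    mask_data: np.ndarray,
    affine: np.ndarray,
    threshold_ml: float = 0.0,
) -> np.ndarray:
    """48 binary flags: 1 iff the cell overlap volume exceeds threshold_ml."""
    if threshold_ml < 0:
        raise ValueError("threshold_ml must be >= 0")
    volumes = voxelize_mask(grid, mask_data, affine)
    return (volumes > threshold_ml).astype(np.int8)


def build_matrix(
    grid: BrainGrid,
    cohort,
    threshold_ml: float = 0.0,
    masks: Optional[Mapping[str, tuple[np.ndarray, np.ndarray]]] = None,
) -> InvolvementMatrix:
    """One involvement row per patient.

    ``masks`` optionally supplies in-memory ``id -> (data, affine)`` pairs
    (e.g. for synthetic cohorts); otherwise each patient's ``mask_path`` is
    read as NIfTI.  A patient whose mask cannot be processed is recorded in
    ``failures`` and dropped from the matrix; the run continues.
    """
    rows: dict[str, np.ndarray] = {}
    failures: dict[str, str] = {}
    for patient in cohort:
        try:
            if masks is not None and patient.id in masks:
                data, affine = masks[patient.id]
            else:
                if patient.mask_path is None:
                    raise FileNotFoundError("no mask_path for patient")
                img = nib.load(str(patient.mask_path))
                data = np.asarray(img.dataobj)
                affine = img.affine
            rows[patient.id] = involvement_vector(grid, data, affine, threshold_ml)
        except Exception as exc:  # recorded, not fatal: partial runs are usable
            failures[patient.id] = f"{type(exc).__name__}: {exc}"
            logger.warning("involvement failed for patient %s: %s", patient.id, exc)
    if not rows:
        raise ValueError("no patient mask could be processed")
    frame = pd.DataFrame.from_dict(rows, orient="index", columns=grid.labels)
    frame.index.name = "id"
    matrix = InvolvementMatrix(frame, threshold_ml, failures)
    logger.info(
        "involvement matrix: %d patients, median %d cells involved, %d failures",
        len(frame),
        int(matrix.patient_counts.median()),
        len(failures),
    )
    return matrix
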