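"""Cohort table I/O, validation and descriptive summaries.

The cohort table is a UTF-8 comma-separated file with a mandatory header::

    id,diagnosis,grade,sex,age_years,volume_ml,border,seizure[,mask_path][,side]

``diagnosis`` ∈ {astrocytoma, oligodendroglioma}; ``grade`` ∈ {2, 3};
``sex`` ∈ {male, female}; ``border`` ∈ {diffuse, sharp} or empty (missing
border is allowed and excluded listwise from border analyses); ``seizure``
is encoded yes/no.  ``mask_path`` references the patient's binary tumour
mask in template space (NIfTI); it may be omitted for table-only analyses.
``side`` (left/right/bilateral) is normally derived from mask geometry but
an explicit column overrides the derivation.
"""

from __future__ import annotations

import datetime as _dt
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import nibabel as nib
import numpy as np
import pandas as pd

logger = logging.getLogger("braingrid")

__all__ = [
    "PatientRecord",
    "Cohort",
    "CohortValidationError",
    "load_cohort",
    "write_cohort",
    "summarize_cohort",
    "derive_laterality",
    "round_pct",
]

DIAGNOSES = ("astrocytoma", "oligodendroglioma")
GRADES = (2, 3)
SEXES = ("male", "female")
BORDERS = ("diffuse", "sharp")
SIDES = ("left", "right", "bilateral")

COLUMNS = ["id", "diagnosis", "grade", "sex", "age_years", "volume_ml", "border", "seizure"]


class CohortValidationError(ValueError):
    """Raised with row-level diagnostics when the cohort table is invalid."""

    def __init__(self, problems: list[str]):
        self.problems = problems
        super().__init__("; ".join(problems))


@dataclass
class PatientRecord:
    id: str
    diagnosis: str
    grade: int
    sex: str
    age_years: float
    volume_ml: float
    seizure: bool
    border: Optional[str] = None
    mask_path: Optional[Path] = None
    side: Optional[str] = None

    def validate(self) -> list[str]:
        problems = []
        if self.diagnosis not in DIAGNOSES:
            problems.append(f"patient {self.id}: unknown diagnosis {self.diagnosis!r}")
        if self.grade not in GRADES:
            problems.append(f"patient {self.id}: grade must be 2 or 3, got {self.grade!r}")
        if self.sex not in SEXES:
            problems.append(f"patient {self.id}: unknown sex {self.sex!r}")
        if self.border is not None and self.border not in BORDERS:
            problems.append(f"patient {self.id}: unknown border {self.border!r}")
        if self.side is not None and self.side not in SIDES:
            problems.append(f"patient {self.id}: unknown side {self.side!r}")
        if not (self.volume_ml >= 0):
            problems.append(f"patient {self.id}: volume_ml must be >= 0")
        if not np.isfinite(self.age_years):
            problems.append(f"patient {self.id}: non-finite age")
        return problems


@dataclass
class Cohort:
    patients: list[PatientRecord]
    provenance: str = ""

    def __post_init__(self) -> None:
        if not self.patients:
            raise CohortValidationError(["cohort is empty"])
        ids = [p.id for p in self.patients]
        if len(set(ids)) != len(ids):
            dups = sorted({i for i in ids if ids.count(i) > 1})
            raise CohortValidationError([f"duplicate patient id(s): {', '.join(dups)}"])

    def __len__(self) -> int:
        return len(self.patients)

    def __iter__(self):
        return iter(self.patients)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for p in self.patients:
            rows.append(
                {
                    "id": p.id,
                    "diagnosis": p.diagnosis,
                    "grade": p.grade,
                    "sex": p.sex,
                    "age_years": p.age_years,
                    "volume_ml": p.volume_ml,
                    "border": p.border,
                    "seizure": p.seizure,
                    "mask_path": str(p.mask_path) if p.mask_path else None,
                    "side": p.side,
                }
            )
        return pd.DataFrame(rows).set_index("id", drop=False)

    def subset(self, ids) -> "Cohort":
        keep = set(ids)
        return Cohort([p for p in self.patients if p.id in keep], self.provenance)


def _parse_bool(value, row: str, col: str, problems: list[str]) -> bool:
    text = str(value).strip().lower()
    if text in ("yes", "true", "1"):
        return True
    if text in ("no", "false", "0"):
        return False
    problems.append(f"row {row}: field {col!r} must be yes/no, got {value!r}")
    return False


def load_cohort(table_path, mask_dir=None, *, require_masks: bool = False) -> Cohort:
    """Read and validate the cohort CSV.

    ``mask_dir`` resolves relative ``mask_path`` entries.  All row-level
    problems are collected and raised together as
    :class:`CohortValidationError`.
    """
    table_path = Path(table_path)
    frame = pd.read_csv(table_path, dtype=str, keep_default_na=False)
    missing = [c for c in COLUMNS if c not in frame.columns]
    if missing:
        raise CohortValidationError([f"missing mandatory column(s): {', '.join(missing)}"])
    problems: list[str] = []
    patients: list[PatientRecord] = []
    for i, row in frame.iterrows():
        rid = row["id"].strip() or f"<row {i}>"
        row_problems: list[str] = []
        for col in ("id", "diagnosis", "sex", "seizure", "grade", "age_years", "volume_ml"):
            if not str(row[col]).strip():
                row_problems.append(f"row {rid}: missing mandatory field {col!r}")
        if row_problems:
            problems.extend(row_problems)
            continue
        try:
            grade = int(row["grade"])
        except ValueError:
            problems.append(f"row {rid}: grade must be an integer, got {row['grade']!r}")
            continue
        try:
            age = float(row["age_years"])
            volume = float(row["volume_ml"])
        except ValueError:
            problems.append(f"row {rid}: non-numeric age or volume")
            continue
        mask_path = None
        raw_mask = str(row.get("mask_path", "")).strip()
        if raw_mask:
            mask_path = Path(raw_mask)
            if mask_dir is not None and not mask_path.is_absolute():
                mask_path = Path(mask_dir) / mask_path
        rec = PatientRecord(
            id=rid,
            diagnosis=row["diagnosis"].strip().lower(),
            grade=grade,
            sex=row["sex"].strip().lower(),
            age_years=age,
            volume_ml=volume,
            border=(row["border"].strip().lower() or None),
            seizure=_parse_bool(row["seizure"], rid, "seizure", problems),
            mask_path=mask_path,
            side=(str(row.get("side", "")).strip().lower() or None),
        )
        problems.extend(rec.validate())
        if require_masks:
            if rec.mask_path is None:
                problems.append(f"patient {rid}: mask_path required but missing")
            elif not rec.mask_path.exists():
                problems.append(f"patient {rid}: mask file not found: {rec.mask_path}")
        patients.append(rec)
    if problems:
        raise CohortValidationError(problems)
    cohort = Cohort(patients, provenance=f"{table_path} @ {_dt.datetime.now().isoformat()}")
    logger.info("loaded cohort: %d patients from %s", len(cohort), table_path)
    return cohort


def write_cohort(cohort: Cohort, table_path) -> Path:
    """Write the cohort CSV in the documented dialect (booleans as yes/no)."""
    table_path = Path(table_path)
    frame = cohort.to_frame().copy()
    frame["seizure"] = frame["seizure"].map({True: "yes", False: "no"})
    frame = frame.fillna("")
    frame.to_csv(table_path, index=False)
    return table_path


def round_pct(numerator: float, denominator: float) -> int:
    """Integer percent, half away from zero (presentation rounding)."""
    if denominator == 0:
        return 0
    pct = 100.0 * numerator / denominator
    return int(np.floor(pct + 0.5)) if pct >= 0 else -int(np.floor(-pct + 0.5))


def derive_laterality(mask_data: np.ndarray, affine: np.ndarray) -> str:
    """left / right / bilateral from mask geometry: any tumour voxel centre
    at x < 0 counts left, any at x > 0 counts right; both → bilateral."""
    idx = np.argwhere(np.asarray(mask_data) > 0)
    if idx.size == 0:
        raise ValueError("empty mask has no laterality")
    x = nib.affines.apply_affine(np.asarray(affine, float), idx)[:, 0]
    has_left = bool((x < 0).any())
    has_right = bool((x > 0).any())
    if has_left and has_right:
        return "bilateral"
    return "left" if has_left else "right"


def summarize_cohort(cohort: Cohort) -> dict:
    """Descriptive summary mirroring a clinical characteristics table.

    Counts and whole-cohort integer percentages by seizure status within
    sex, diagnosis × grade, border and side, plus mean/median (min-max) of
    age and tumour volume.  Patient order does not affect the result.
    """
    df = cohort.to_frame()
    n = len(df)
    out: dict = {"n": n}
    n_seiz = int(df["seizure"].sum())
    out["seizures"] = {"count": n_seiz, "pct": round_pct(n_seiz, n)}

    def _group(col: str, values) -> dict:
        block = {}
        for v in values:
            sub = df[df[col] == v]
            with_seiz = int(sub["seizure"].sum())
            block[v] = {
                "count": len(sub),
                "pct": round_pct(len(sub), n),
                "with_seizures": with_seiz,
                "with_seizures_pct": round_pct(with_seiz, n),
            }
        return block

    out["sex"] = _group("sex", SEXES)
    out["border"] = _group("border", BORDERS)
    out["border"]["missing"] = {"count": int(df["border"].isna().sum())}
    if df["side"].notna().any():
        out["side"] = _group("side", SIDES)
    dg = {}
    for d in DIAGNOSES:
        for g in GRADES:
            sub = df[(df["diagnosis"] == d) & (df["grade"] == g)]
            dg[f"{d} grade {g}"] = {
                "count": len(sub),
                "pct": round_pct(len(sub), n),
                "with_seizures": int(sub["seizure"].sum()),
                "with_seizures_pct": round_pct(int(sub["seizure"].sum()), n),
            }
    out["diagnosis_grade"] = dg
    for col in ("age_years", "volume_ml"):
        out[col] = {
            "mean": float(df[col].mean()),
            "median": float(df[col].median()),
            "min": float(df[col].min()),
            "max": float(df[col].max()),
        }
    return out


def summary_text(summary: dict) -> str:
    """Human-readable rendering of :func:`summarize_cohort` output."""
    lines = [f"Patients: {summary['n']}"]
    s = summary["seizures"]
    lines.append(f"With seizures: {s['count']} ({s['pct']}%)")
    for block in ("sex", "diagnosis_grade", "border"):
        lines.append(block.replace("_", " ").capitalize() + ":")
        for key, v in summary[block].items():
            if "pct" not in v:
                lines.append(f"  {key}: {v['count']}")
                continue
            lines.append(
                f"  {key}: {v['count']} ({v['pct']}%), with seizures "
                f"{v['with_seizures']} ({v['with_seizures_pct']}%)"
            )
    for col in ("age_years", "volume_ml"):
        v = summary[col]
        lines.append(
            f"{col}: mean {v['mean']:.1f}, median {v['median']:.1f} "
            f"({v['min']:.1f}-{v['max']:.1f})"
        )
    return "\n".join(lines)
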