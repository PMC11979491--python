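"""End-to-end orchestration: grid → involvement → maps → scans → tracts.

``run_pipeline`` executes the stages on a loaded or simulated cohort and
writes a versioned result bundle: CSV tables, NIfTI volumes and a JSON run
log holding the parameters, the seed and per-stage status, so every bundle
is reproducible from its embedded config.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from . import __version__
from .cohort import load_cohort, summarize_cohort, summary_text
from .config import RunConfig
from .grid import build_grid
from .involvement import build_matrix
from .occurrence import ReferenceGeometry, cell_frequency_table, group_occurrence, peak_occurrence
from .simulate import SimulationConfig, generate_cohort
from .stats import scan_frame, stepwise_multivariate, univariate_scan
from .tracts import cell_tract_membership, load_atlas, occurrence_tract_profile

logger = logging.getLogger("braingrid")

__all__ = ["ResultBundle", "run_pipeline"]


@dataclass
class ResultBundle:
    out_dir: Path
    status: str  # "success" | "partial" | "fail"
    stages: dict = field(default_factory=dict)
    errors: list = field(default_factory=list)

    @property
    def exit_code(self) -> int:
        return {"success": 0, "partial": 2}.get(self.status, 1)


def run_pipeline(config: RunConfig) -> ResultBundle:
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    bundle = ResultBundle(out_dir, "success")
    log: dict = {
        "version": __version__,
        "seed": config.seed,
        "parameters": {
            "threshold_ml": config.threshold_ml,
            "min_involved": config.min_involved,
            "p_enter": config.p_enter,
            "p_remove": config.p_remove,
            "adjust": config.adjust,
            "spacing_mm": config.spacing_mm,
        },
        "stages": {},
    }

    def stage(name):
        def wrap(fn):
            try:
                info = fn() or {}
                log["stages"][name] = {"status": "ok", **info}
                logger.info("stage %s: ok %s", name, info)
            except Exception as exc:
                log["stages"][name] = {"status": "error", "error": str(exc)}
                bundle.errors.append({"stage": name, "error": str(exc)})
                bundle.status = "partial"
                logger.error("stage %s failed: %s", name, exc)
            return None

        return wrap

    grid = build_grid(config.grid_spec)
    reference = ReferenceGeometry.from_box(config.grid_spec.bounding_box, config.spacing_mm)
    masks = None

    # --- cohort ----------------------------------------------------------
    if config.simulation is not None:
        sim = SimulationConfig(seed=config.seed, **config.simulation)
        synthetic = generate_cohort(sim)
        cohort, masks = synthetic.cohort, synthetic.masks
        synthetic.truth.to_csv(out_dir / "truth.csv", index=False)
        log["stages"]["simulate"] = {"status": "ok", "n": len(cohort)}
    else:
        cohort = load_cohort(config.cohort_path, config.mask_dir)
    df = cohort.to_frame()

    @stage("grid")
    def _grid():
        grid.to_nifti(reference.shape, reference.affine).to_filename(
            str(out_dir / "grid_labels.nii")
        )
        return {"cells": len(grid.cells)}

    @stage("summary")
    def _summary():
        summary = summarize_cohort(cohort)
        (out_dir / "cohort_summary.json").write_text(json.dumps(summary, indent=2))
        (out_dir / "cohort_summary.txt").write_text(summary_text(summary))
        return {"n": summary["n"]}

    matrix = None

    @stage("involvement")
    def _involve():
        nonlocal matrix
        matrix = build_matrix(grid, cohort, config.threshold_ml, masks=masks)
        matrix.write(out_dir / "involvement.csv", {"seed": config.seed})
        if matrix.failures:
            raise RuntimeError(f"{len(matrix.failures)} mask(s) failed")
        return {"patients": len(matrix.frame)}

    if matrix is None:
        # involvement failed outright: nothing downstream can run
        bundle.status = "fail"
        _finalize(bundle, log, out_dir)
        return bundle

    @stage("occurrence")
    def _occ():
        def mask_of(pid):
            if masks is not None and pid in masks:
                return masks[pid]
            img = nib.load(str(df.loc[pid, "mask_path"]))
            return np.asarray(img.dataobj), img.affine

        info = {}
        for group, flag in (("seizure", True), ("no_seizure", False)):
            ids = [p.id for p in cohort if p.seizure == flag]
            if not ids:
                continue
            occ = group_occurrence([mask_of(i) for i in ids], reference, group)
            occ.to_nifti().to_filename(str(out_dir / f"occurrence_{group}.nii"))
            peak, cell = peak_occurrence(occ, grid)
            info[group] = {"n": occ.n, "peak": peak, "peak_cell": cell}
        freq = cell_frequency_table(grid, matrix, df["seizure"])
        freq.to_csv(out_dir / "cell_frequency.csv", index=False)
        return info

    @stage("scan")
    def _scan():
        results = univariate_scan(
            matrix, df["seizure"], min_involved=config.min_involved, adjust=config.adjust
        )
        frame = scan_frame(results, adjust=config.adjust)
        frame.to_csv(out_dir / "univariate_scan.csv")
        significant = frame.loc[(frame["flag"] == "ok") & (frame["p"] < 0.05)]
        return {
            "estimable": int((frame["flag"] == "ok").sum()),
            "significant": sorted(significant.index),
        }

    @stage("stepwise")
    def _stepwise():
        scan = pd.read_csv(out_dir / "univariate_scan.csv").set_index("cell")
        chosen = scan.loc[(scan["flag"] == "ok") & (scan["p"] < 0.05)].index.tolist()
        if not chosen:
            return {"skipped": "no univariately significant cells"}
        data = pd.concat(
            [
                matrix.frame[chosen],
                df.loc[matrix.frame.index, ["seizure", "volume_ml"]],
                (df.loc[matrix.frame.index, "sex"] == "male").astype(int).rename("male"),
                (df.loc[matrix.frame.index, "border"] == "diffuse").astype(float).rename(
                    "diffuse_border"
                ),
            ],
            axis=1,
        ).dropna()
        result = stepwise_multivariate(
            data,
            candidates=chosen,
            outcome="seizure",
            confounders=["male", "volume_ml", "diffuse_border"],
            p_enter=config.p_enter,
            p_remove=config.p_remove,
        )
        payload = {
            "selected": result.selected,
            "confounders": result.confounders,
            "steps": result.steps,
            "p_enter": result.p_enter,
            "p_remove": result.p_remove,
            "flag": result.flag,
        }
        if result.table is not None:
            payload["model"] = json.loads(result.table.to_json(orient="index"))
        (out_dir / "stepwise.json").write_text(json.dumps(payload, indent=2))
        return {"selected": result.selected}

    if config.atlas_manifest is not None:

        @stage("tracts")
        def _tracts():
            atlas = load_atlas(config.atlas_manifest)
            cell_tract_membership(grid, atlas).to_csv(
                out_dir / "cell_tract_membership.csv", index=False
            )
            for group in ("seizure", "no_seizure"):
                path = out_dir / f"occurrence_{group}.nii"
                if not path.exists():
                    continue
                img = nib.load(str(path))
                from .occurrence import OccurrenceMap

                occ = OccurrenceMap(np.asarray(img.dataobj), reference, group, 0)
                occurrence_tract_profile(occ, atlas).to_csv(
                    out_dir / f"tract_profile_{group}.csv"
                )
            return {"tracts": len(atlas)}

    _finalize(bundle, log, out_dir)
    return bundle


def _finalize(bundle: ResultBundle, log: dict, out_dir: Path) -> None:
    log["status"] = bundle.status
    log["errors"] = bundle.errors
    (out_dir / "run_log.json").write_text(json.dumps(log, indent=2, default=str))
    bundle.stages = log["stages"]
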