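"""Run configuration: YAML schema, validation and construction.

A run config is a YAML document with these blocks (all optional unless a
command needs them)::

    paths:
      cohort: cohort.csv          # cohort table
      mask_dir: masks/            # resolves relative mask_path entries
      atlas: atlas/atlas.yaml     # tract manifest (optional)
      out: results/               # output bundle directory
    grid:                         # omit for the fractional default
      mediolateral_planes: [-36.0, 0.0, 36.0]
      anteroposterior_planes: [12.0, -48.0]
      dorsoventral_planes: [48.0, 12.0, -24.0]
      bounding_box: [[-72, 72], [-108, 72], [-60, 84]]
    involvement:
      threshold_ml: 0.0
    statistics:
      min_involved: 1
      p_enter: 0.05
      p_remove: 0.10
      adjust: none                # or bh
    occurrence:
      spacing_mm: 2.0
    simulation:                   # optional: simulate instead of loading
      n_patients: 93
    seed: 0
    verbosity: info
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import yaml

from .grid import GridSpec, GridSpecError

logger = logging.getLogger("braingrid")

__all__ = ["RunConfig", "load_config", "validate_config"]


@dataclass
class RunConfig:
    cohort_path: Optional[Path] = None
    mask_dir: Optional[Path] = None
    atlas_manifest: Optional[Path] = None
    out_dir: Path = Path("braingrid-results")
    grid_spec: GridSpec = field(default_factory=GridSpec.default)
    threshold_ml: float = 0.0
    min_involved: int = 1
    p_enter: float = 0.05
    p_remove: float = 0.10
    adjust: Optional[str] = None
    spacing_mm: float = 2.0
    simulation: Optional[dict] = None
    seed: int = 0
    verbosity: str = "info"


def _build(raw: dict, base: Path) -> RunConfig:
    paths = raw.get("paths", {}) or {}

    def p(key):
        v = paths.get(key)
        if v is None:
            return None
        path = Path(v)
        return path if path.is_absolute() else base / path

    grid_block = raw.get("grid")
    if grid_block:
        spec = GridSpec(
            tuple(grid_block["mediolateral_planes"]),
            tuple(grid_block["anteroposterior_planes"]),
            tuple(grid_block["dorsoventral_planes"]),
            tuple(tuple(b) for b in grid_block.get("bounding_box", GridSpec.default().bounding_box)),
            grid_block.get("template", "MNI152"),
        )
    else:
        spec = GridSpec.default()
    stats = raw.get("statistics", {}) or {}
    adjust = stats.get("adjust")
    if adjust in ("none", None):
        adjust = None
    return RunConfig(
        cohort_path=p("cohort"),
        mask_dir=p("mask_dir"),
        atlas_manifest=p("atlas"),
        out_dir=p("out") or base / "braingrid-results",
        grid_spec=spec,
        threshold_ml=float((raw.get("involvement", {}) or {}).get("threshold_ml", 0.0)),
        min_involved=int(stats.get("min_involved", 1)),
        p_enter=float(stats.get("p_enter", 0.05)),
        p_remove=float(stats.get("p_remove", 0.10)),
        adjust=adjust,
        spacing_mm=float((raw.get("occurrence", {}) or {}).get("spacing_mm", 2.0)),
        simulation=raw.get("simulation"),
        seed=int(raw.get("seed", 0)),
        verbosity=str(raw.get("verbosity", "info")),
    )


def load_config(path) -> RunConfig:
    raw = yaml.safe_load(Path(path).read_text()) or {}
    return _build(raw, Path(path).resolve().parent)


def validate_config(path) -> list[str]:
    """Schema-check a config file; returns a list of diagnostics (empty when
    valid).  A dry run: nothing is executed or written."""
    diagnostics: list[str] = []
    try:
        raw = yaml.safe_load(Path(path).read_text())
    except yaml.YAMLError as exc:
        return [f"malformed YAML: {exc}"]
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        return ["config root must be a mapping"]
    try:
        cfg = _build(raw, Path(path).resolve().parent)
    except (KeyError, TypeError, ValueError, GridSpecError) as exc:
        return [f"config error: {exc}"]
    if not (0 < cfg.p_enter <= cfg.p_remove < 1):
        diagnostics.append(
            f"statistics: need 0 < p_enter <= p_remove < 1, "
            f"got p_enter={cfg.p_enter}, p_remove={cfg.p_remove}"
        )
    if cfg.threshold_ml < 0:
        diagnostics.append("involvement: threshold_ml must be >= 0")
    if cfg.min_involved < 1:
        diagnostics.append("statistics: min_involved must be >= 1")
    if cfg.spacing_mm <= 0:
        diagnostics.append("occurrence: spacing_mm must be > 0")
    if cfg.adjust not in (None, "bh", "fdr_bh"):
        diagnostics.append(f"statistics: unknown adjust {cfg.adjust!r}")
    if cfg.simulation is None:
        if cfg.cohort_path is None:
            diagnostics.append("paths: cohort is required unless a simulation block is given")
        elif not cfg.cohort_path.exists():
            diagnostics.append(f"paths: cohort table not found: {cfg.cohort_path}")
        if cfg.mask_dir is not None and not cfg.mask_dir.exists():
            diagnostics.append(f"paths: mask_dir not found: {cfg.mask_dir}")
    if cfg.atlas_manifest is not None and not cfg.atlas_manifest.exists():
        diagnostics.append(f"paths: atlas manifest not found: {cfg.atlas_manifest}")
    return diagnostics
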