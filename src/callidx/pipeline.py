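"""End-to-end pipeline: volumes → CC segmentation → CCI/CCA → group stats.

Also hosts the phantom-study simulator used for validation runs: a pair of
synthetic groups whose only systematic difference is arch thinning
(atrophy), pushed through the identical measurement path as real data
would be.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .exceptions import CallidxError, ValidationError
from .metrics import CCIResult, measure_stack
from .segmentation import (
    TemplateAtlas,
    default_template,
    extract_midsagittal_slices,
    segment_cc,
)
from .synthetic import CCShapeSpec, generate_cc_mask, generate_wm_context
from .volume import BinaryVolume, read_volume, write_volume

log = logging.getLogger(__name__)

__all__ = [
    "PipelineConfig",
    "PipelineResult",
    "analyze_subject",
    "run_pipeline",
    "simulate_phantom_study",
]


@dataclass
class PipelineConfig:
    """Everything one pipeline run needs, loadable from YAML."""

    manifest: str | Path
    out_dir: str | Path
    template: str | Path | None = None  # None → packaged default template
    cohort_table: str | Path | None = None
    dilation_mm: float = 3.0
    n_slices: int = 7
    seed: int = 0
    group_col: str = "group"
    outcomes: list[str] = field(default_factory=lambda: ["cci", "cca_mm2"])
    covariates: list[str] = field(default_factory=list)
    group_order: tuple[str, str] | None = None
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if self.n_slices % 2 == 0 or self.n_slices < 1:
            raise ValidationError("n_slices must be a positive odd integer")
        if self.dilation_mm < 0:
            raise ValidationError("dilation_mm must be ≥ 0")
        if self.group_order is not None:
            self.group_order = tuple(self.group_order)  # type: ignore[assignment]

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)


@dataclass
class PipelineResult:
    metrics: pd.DataFrame
    stats: pd.DataFrame | None
    qc: dict
    failures: dict[str, str]

    @property
    def ok(self) -> bool:
        return not self.failures


def _load_template(spec: str | Path | None) -> TemplateAtlas:
    if spec is None or str(spec) == "default":
        return default_template()
    vol = read_volume(spec)
    return TemplateAtlas(cc_mask=vol, midline_index=vol.shape[0] // 2)


def analyze_subject(
    wm: BinaryVolume,
    template: TemplateAtlas,
    dilation_mm: float = 3.0,
    n_slices: int = 7,
) -> CCIResult:
    """Full measurement chain for one subject WM mask."""
    cc, transform = segment_cc(wm, template, dilation_mm=dilation_mm)
    stack = extract_midsagittal_slices(cc, n_slices=n_slices)
    log.info(
        "slab slices %s (dilation %.2f mm, affine scale %.4f)",
        stack.indices, dilation_mm, transform.scale,
    )
    return measure_stack(stack, transform)


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Run every subject in the manifest, merge the cohort table, run stats.

    Per-subject failures are collected and reported — nothing is silently
    skipped.  Outputs (metrics.csv, stats.csv, qc.json) are written to
    ``config.out_dir``; reruns with identical config and inputs are
    byte-identical.
    """
    logging.basicConfig(level=config.log_level)
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    manifest = pd.read_csv(config.manifest)
    if manifest.empty:
        raise CallidxError("empty input manifest")
    for col in ("subject_id", "wm_path"):
        if col not in manifest.columns:
            raise CallidxError(f"manifest lacks required column {col!r}")

    template = _load_template(config.template)
    rows: list[dict] = []
    qc: dict[str, dict] = {
        "params": {
            "dilation_mm": config.dilation_mm,
            "n_slices": config.n_slices,
            "template": str(config.template or "default"),
            "seed": config.seed,
        },
        "subjects": {},
    }
    failures: dict[str, str] = {}
    for rec in manifest.itertuples(index=False):
        sid = str(rec.subject_id)
        try:
            wm = read_volume(rec.wm_path)
            res = analyze_subject(
                wm, template, config.dilation_mm, config.n_slices
            )
        except Exception as exc:  # noqa: BLE001 — reported, not swallowed
            failures[sid] = f"{type(exc).__name__}: {exc}"
            log.error("subject %s failed: %s", sid, failures[sid])
            continue
        row = {
            "subject_id": sid,
            "cci": res.cci,
            "cca_mm2": res.cca_mm2,
            "cca_template_normalized_mm2": res.cca_template_normalized_mm2,
            "n_slices_used": res.n_slices_used,
        }
        if hasattr(rec, "group"):
            row["group"] = rec.group
        rows.append(row)
        qc["subjects"][sid] = res.to_dict()

    metrics = pd.DataFrame(rows)
    if config.cohort_table is not None and not metrics.empty:
        cohort = pd.read_csv(config.cohort_table)
        metrics = metrics.merge(
            cohort, on="subject_id", how="left", suffixes=("", "_cohort")
        )

    stats_df = None
    if not metrics.empty and config.outcomes and config.group_col in metrics:
        from .stats import batch_ancova

        stats_df = batch_ancova(
            metrics,
            [o for o in config.outcomes if o in metrics.columns],
            covariates=config.covariates,
            group_col=config.group_col,
            group_order=config.group_order,
        )
        stats_df.to_csv(out_dir / "stats.csv", index=False)

    metrics.to_csv(out_dir / "metrics.csv", index=False)
    qc["failures"] = failures
    with open(out_dir / "qc.json", "w") as fh:
        json.dump(qc, fh, indent=2, sort_keys=True)
    return PipelineResult(metrics=metrics, stats=stats_df, qc=qc, failures=failures)


def simulate_phantom_study(
    out_dir: str | Path,
    n_per_group: int = 5,
    atrophy: tuple[float, float] = (0.8, 1.0),
    group_labels: tuple[str, str] = ("BRRMS", "HC"),
    boundary_jitter_sd: float = 0.3,
    voxel_size: float = 1.0,
    n_distractors: int = 3,
    seed: int = 0,
) -> Path:
    """Write a two-group phantom study to disk; returns the manifest path.

    Group 0 carries the atrophy factor ``atrophy[0]`` (thinned arch), group
    1 ``atrophy[1]``.  Each subject gets a WM NIfTI (CC arch + distractor
    blobs), an analytic-truth JSON sidecar, and a manifest row.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for gi, (label, af) in enumerate(zip(group_labels, atrophy)):
        for i in range(n_per_group):
            subj_seed = seed + 1000 * gi + i
            spec = CCShapeSpec(
                atrophy_factor=af,
                voxel_size=(voxel_size,) * 3,
                boundary_jitter_sd=boundary_jitter_sd,
                seed=subj_seed,
            )
            cc, truth = generate_cc_mask(spec)
            wm = generate_wm_context(cc, spec, n_distractors=n_distractors)
            sid = f"{label}_{i:03d}"
            wm_path = out_dir / f"{sid}_wm.nii.gz"
            write_volume(wm, wm_path)
            with open(out_dir / f"{sid}_truth.json", "w") as fh:
                json.dump(truth.to_dict(), fh, indent=2)
            rows.append(
                {"subject_id": sid, "wm_path": str(wm_path), "group": label}
            )
    manifest = out_dir / "manifest.csv"
    pd.DataFrame(rows).to_csv(manifest, index=False)
    return manifest
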