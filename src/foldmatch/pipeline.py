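"""End-to-end orchestration: cohort summaries, area regressions, per-subject
longitudinal morphometry and the group analysis.

Units are mm internally; area regressions are reported in cm² per week and
ages in decimal weeks, the conventions of the developmental literature.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats as sps

from . import curvature as curv
from .cpd import Correspondence
from .groupstats import GroupSample, StatMap, hotelling_t2_map, \
    longitudinal_group_analysis, map_group_to_reference, mean_shape
from .matching import MatchConfig, match_pipeline
from .mesh import SubjectRecord, TriangleMesh, enclosed_volume, read_mesh, \
    surface_area, write_mesh

__all__ = [
    "AnalysisConfig",
    "cohort_summary",
    "area_vs_age_regression",
    "run_longitudinal_subject",
    "run_group_analysis",
]

log = logging.getLogger(__name__)


@dataclass
class AnalysisConfig:
    """Declarative configuration of a full run (JSON-serializable)."""

    metadata_path: str = ""
    mesh_dir: str = ""
    output_dir: str = "foldmatch_out"
    k: int = 5
    curvature_ring: int = 2
    link_fraction: float = 0.2
    link_weight_factor: float = 1.0
    cpd_subsample: int = 3000
    cpd_outlier_weight: float = 0.1
    cpd_use_scale: bool = True
    reference_subject: str = ""   # default: first subject in the table
    p_thresholds: tuple = (0.05, 0.5)
    seed: int = 0

    def match_config(self) -> MatchConfig:
        return MatchConfig(
            k=self.k,
            link_fraction=self.link_fraction,
            link_weight_factor=self.link_weight_factor,
            cpd_subsample=self.cpd_subsample,
            cpd_outlier_weight=self.cpd_outlier_weight,
            cpd_use_scale=self.cpd_use_scale,
            seed=self.seed,
        )

    def hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]

    @classmethod
    def from_json(cls, path: str | Path) -> "AnalysisConfig":
        data = json.loads(Path(path).read_text())
        return cls(**data)


def cohort_summary(records: list[SubjectRecord]) -> pd.DataFrame:
    """Mean and sample standard deviation (ddof=1) of the cohort ages.

    Values are reported to one decimal in weeks, the convention of clinical
    cohort tables.
    """
    if len(records) < 2:
        raise ValueError("need at least 2 records")
    data = {
        "ga_birth": [r.ga_birth for r in records],
        "ega_scan1": [r.ega_scan1 for r in records],
        "ega_scan2": [r.ega_scan2 for r in records],
    }
    rows = []
    for name, values in data.items():
        arr = np.asarray(values)
        rows.append({
            "variable": name,
            "mean_weeks": round(float(arr.mean()), 1),
            "sd_weeks": round(float(arr.std(ddof=1)), 1),
            "n": len(arr),
        })
    return pd.DataFrame(rows).set_index("variable")


def area_vs_age_regression(table: pd.DataFrame) -> pd.DataFrame:
    """Per-group OLS of surface area (cm²) against EGA (weeks).

    ``table`` needs columns ``area_cm2``, ``ega_weeks`` and optionally
    ``region`` / ``hemisphere`` grouping columns.  Groups with fewer than
    3 points are skipped with a warning.  Output has one row per group
    with slope (cm²/week), intercept and R².
    """
    group_cols = [c for c in ("region", "hemisphere") if c in table.columns]
    groups = table.groupby(group_cols) if group_cols else [(("all",), table)]
    rows = []
    for key, sub in groups:
        if len(sub) < 3:
            log.warning("group %s has < 3 points; skipped", key)
            continue
        res = sps.linregress(sub["ega_weeks"], sub["area_cm2"])
        row = dict(zip(group_cols, key if isinstance(key, tuple) else (key,)))
        row.update({
            "slope_cm2_per_week": float(res.slope),
            "intercept_cm2": float(res.intercept),
            "r_squared": float(res.rvalue ** 2),
            "n": len(sub),
        })
        rows.append(row)
    if not rows:
        raise ValueError("no group had enough points for a regression")
    return pd.DataFrame(rows)


@dataclass
class SubjectResult:
    """Outputs of one subject's longitudinal morphometry run."""

    subject_id: str
    corr: Correspondence
    delta_mean: np.ndarray
    delta_gaussian: np.ndarray
    area_change: np.ndarray
    bending_energy_change: np.ndarray
    area_early_mm2: float
    area_late_mm2: float
    volume_early_mm3: float
    volume_late_mm3: float


def run_longitudinal_subject(
    config: AnalysisConfig,
    subject: SubjectRecord,
    mesh_early: TriangleMesh | None = None,
    mesh_late: TriangleMesh | None = None,
    write_outputs: bool = True,
) -> SubjectResult:
    """Match one subject's two scans and compute all change maps.

    Meshes may be passed directly (synthetic cohorts) or read from
    ``{mesh_dir}/{subject_id}_scan{1,2}.vtk``.  All fields are expressed on
    the early mesh; outputs are written as VTK scalar arrays plus a
    correspondence table when ``write_outputs`` is set.
    """
    t0 = time.perf_counter()
    if mesh_early is None or mesh_late is None:
        base = Path(config.mesh_dir)
        early_path = base / f"{subject.subject_id}_scan1.vtk"
        late_path = base / f"{subject.subject_id}_scan2.vtk"
        if not early_path.exists() or not late_path.exists():
            raise FileNotFoundError(
                f"{subject.subject_id}: missing mesh file "
                f"({early_path.name} / {late_path.name})"
            )
        mesh_early = read_mesh(early_path)
        mesh_late = read_mesh(late_path)

    corr = match_pipeline(mesh_early, mesh_late, config.match_config())
    log.info("%s: matching done in %.1fs", subject.subject_id,
             time.perf_counter() - t0)

    vol_early = subject.volume_scan1_mm3 or enclosed_volume(mesh_early)
    vol_late = subject.volume_scan2_mm3 or enclosed_volume(mesh_late)
    field_early = curv.principal_curvatures(mesh_early, config.curvature_ring)
    field_late = curv.principal_curvatures(mesh_late, config.curvature_ring)
    delta_m, delta_g = curv.curvature_change(
        field_early, field_late, corr, vol_early, vol_late)
    ratio = curv.local_area_change(mesh_early, mesh_late, corr)
    delta_e = curv.bending_energy_change(
        field_early, field_late, corr, ratio, mesh_early)
    result = SubjectResult(
        subject.subject_id, corr, delta_m, delta_g, ratio, delta_e,
        surface_area(mesh_early), surface_area(mesh_late),
        vol_early, vol_late,
    )
    if write_outputs:
        out = Path(config.output_dir) / subject.subject_id
        out.mkdir(parents=True, exist_ok=True)
        write_mesh(mesh_early, out / "early_changes.vtk", point_data={
            "delta_mean_curvature": delta_m,
            "delta_gaussian_curvature": delta_g,
            "local_area_change": ratio,
            "bending_energy_change": delta_e,
            "mean_curvature_early": field_early.mean,
        })
        corr.save(out / "correspondence.txt")
        (out / "run.json").write_text(json.dumps({
            "config_hash": config.hash(),
            "subject": subject.subject_id,
            "area_early_mm2": result.area_early_mm2,
            "area_late_mm2": result.area_late_mm2,
            "volume_early_mm3": vol_early,
            "volume_late_mm3": vol_late,
            "seconds": time.perf_counter() - t0,
        }, indent=2))
    log.info("%s: morphometry done in %.1fs total", subject.subject_id,
             time.perf_counter() - t0)
    return result


def run_group_analysis(
    config: AnalysisConfig,
    early_meshes: list[TriangleMesh],
    late_meshes: list[TriangleMesh],
    subject_ids: list[str],
    patch_labels: np.ndarray | None = None,
    write_outputs: bool = True,
) -> dict:
    """Reference-based group contrast of the two time points.

    Builds a GroupSample per time point against the reference subject's
    meshes, runs the longitudinal Hotelling T² contrast, and reports the
    fraction of vertices below each configured p-threshold; when synthetic
    ground-truth ``patch_labels`` (on the reference early mesh) are given,
    per-patch enrichment of significant vertices is added.
    """
    if len(early_meshes) < 3:
        raise ValueError("group analysis needs at least 3 subjects "
                         "(pooled covariance with d = 3)")
    ref_id = config.reference_subject or subject_ids[0]
    ref_idx = subject_ids.index(ref_id)
    mc = config.match_config()
    sample_early = map_group_to_reference(
        early_meshes[ref_idx], early_meshes, mc, subject_ids)
    sample_late = map_group_to_reference(
        late_meshes[ref_idx], late_meshes, mc, subject_ids)
    stat, mean_early, corr = longitudinal_group_analysis(
        sample_early, sample_late, mc)
    report: dict = {
        "reference_subject": ref_id,
        "n_subjects": sample_early.n_subjects,
        "config_hash": config.hash(),
        "fraction_below": {
            str(thr): float((stat.p < thr).mean()) for thr in config.p_thresholds
        },
    }
    if patch_labels is not None:
        inside = np.asarray(patch_labels) >= 0
        sig = stat.p < 0.05
        rate_in = float(sig[inside].mean()) if inside.any() else np.nan
        rate_out = float(sig[~inside].mean()) if (~inside).any() else np.nan
        report["patch_enrichment"] = {
            "rate_inside": rate_in,
            "rate_outside": rate_out,
            "enrichment": rate_in / rate_out if rate_out > 0 else np.inf,
        }
    if write_outputs:
        out = Path(config.output_dir) / "group"
        out.mkdir(parents=True, exist_ok=True)
        write_mesh(mean_early, out / "mean_early_stats.vtk", point_data={
            "t2": stat.t2, "p": stat.p,
        })
        np.savetxt(out / "statmap.txt",
                   np.column_stack([np.arange(len(stat.t2)), stat.t2, stat.p]),
                   header="vertex t2 p", fmt=("%d", "%.6g", "%.6g"))
        (out / "report.json").write_text(json.dumps(report, indent=2))
    report["_statmap"] = stat
    report["_mean_early"] = mean_early
    return report
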