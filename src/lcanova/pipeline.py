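"""End-to-end pipeline: cohort -> omnibus screen -> track pool -> post-hoc.

Stages (mirroring the analysis flow):

A/B  build or load the local-connectome database (QC optional);
C    per-feature Kruskal-Wallis H map, thresholded at factor x Otsu;
D    cluster extent correction, mask negation, terminative-mask tractography;
E    pool ROI from the surviving tracks;
F    per-design post-hoc connectometry (t map, track growing, TIP,
     permutation FDR), constrained by the pool ROI for group comparisons.

Every run is reproducible from (config, seed); the report records the
thresholds actually used (including the computed Otsu values), per-stage
counts, and the SDF pass fraction.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import __version__
from .connectome_db import LocalConnectomeDB, exclude_outlier_subjects
from .connectometry import (
    DesignSpec,
    Finding,
    connectometry_tracks,
    feature_t_map,
    permutation_fdr,
    topology_informed_pruning,
)
from .omnibus import (
    build_track_pool,
    cluster_filter,
    h_supra_mask,
    kw_map,
    negate_mask,
    otsu_threshold,
)
from .tracking import TrackingParams, filter_tracks_by_roi


@dataclass
class OmnibusSettings:
    factor: float = 0.6
    n_bins: int = 256
    min_cluster: int = 20
    connectivity: int = 26


@dataclass
class RunConfig:
    """Full pipeline configuration (the YAML config mirrors these fields)."""

    seed: int = 0
    omnibus: OmnibusSettings = field(default_factory=OmnibusSettings)
    tracking: TrackingParams = field(default_factory=TrackingParams)
    designs: list[DesignSpec] = field(default_factory=list)
    constrain_by_pool: bool = True
    qc_outliers: bool = False
    outlier_z_max: float = 2.0


# Desk-scale preset: full 40^3 phantom but reduced seeding/permutations so an
# end-to-end run stays in the minutes range on one CPU.  The production
# defaults (1e5 seeds, 4000 permutations) live in TrackingParams/DesignSpec.
def desk_preset(seed: int = 0) -> RunConfig:
    return RunConfig(
        seed=seed,
        tracking=TrackingParams(n_seeds=5000, seed=seed),
        designs=[
            DesignSpec(
                mode="group_compare",
                contrast=("EPT", "TC"),
                n_permutations=200,
                seed=seed,
            )
        ],
    )


def validate_config(config: RunConfig) -> list[str]:
    """Return a list of problems; empty iff the config is valid."""
    problems: list[str] = []
    om = config.omnibus
    if not (0 <= om.factor <= 1):
        problems.append("omnibus.factor: must be in [0, 1]")
    if om.n_bins < 2:
        problems.append("omnibus.n_bins: must be at least 2")
    if om.min_cluster < 1:
        problems.append("omnibus.min_cluster: must be at least 1")
    if om.connectivity not in (6, 26):
        problems.append("omnibus.connectivity: must be 6 or 26")
    tr = config.tracking
    if not (0 < tr.angular_threshold_deg <= 90):
        problems.append("tracking.angular_threshold_deg: must be in (0, 90]")
    if tr.min_length >= tr.max_length:
        problems.append("tracking.min_length: must be below max_length")
    if tr.n_seeds < 1:
        problems.append("tracking.n_seeds: must be positive")
    for i, d in enumerate(config.designs):
        if d.t_threshold <= 0:
            problems.append(f"designs[{i}].t_threshold: must be positive")
        if not (0 < d.fdr_level < 1):
            problems.append(f"designs[{i}].fdr_level: must be in (0, 1)")
        if d.length_threshold <= 0:
            problems.append(f"designs[{i}].length_threshold: must be positive")
        if d.n_permutations < 100:
            problems.append(f"designs[{i}].n_permutations: must be at least 100")
    return problems


@dataclass
class DesignResult:
    design: DesignSpec
    sign: str
    n_tracks_grown: int
    n_tracks_after_tip: int
    n_tracks_in_pool: int
    fdr_table: dict[float, float]
    findings: list[Finding]


@dataclass
class RunReport:
    """Per-stage counts and the thresholds actually used."""

    version: str = __version__
    seed: int = 0
    n_subjects: int = 0
    n_features: int = 0
    h_otsu: float = float("nan")
    h_threshold: float = float("nan")
    sdf_pass_fraction: float = float("nan")
    n_supra_voxels: int = 0
    n_cluster_voxels: int = 0
    n_clusters: int = 0
    qa_threshold: float = float("nan")
    n_pool_tracks: int = 0
    n_pool_voxels: int = 0
    design_results: list[DesignResult] = field(default_factory=list)
    excluded_subjects: list[str] = field(default_factory=list)

    def n_findings(self) -> int:
        return sum(len(r.findings) for r in self.design_results)

    def to_json(self, path: str | Path) -> None:
        def clean(obj):
            if isinstance(obj, RunReport):
                d = dataclasses.asdict(obj)
                d["design_results"] = [clean(r) for r in obj.design_results]
                return d
            if isinstance(obj, DesignResult):
                return {
                    "design": dataclasses.asdict(obj.design),
                    "sign": obj.sign,
                    "n_tracks_grown": obj.n_tracks_grown,
                    "n_tracks_after_tip": obj.n_tracks_after_tip,
                    "n_tracks_in_pool": obj.n_tracks_in_pool,
                    "fdr_table": obj.fdr_table,
                    "findings": [
                        {
                            "sign": f.sign,
                            "n_tracks": len(f.tracks),
                            "length_mm": f.length_mm,
                            "fdr": f.fdr,
                        }
                        for f in obj.findings
                    ],
                }
            return obj

        Path(path).write_text(json.dumps(clean(self), indent=1, default=str))


def pool_qa_threshold(db: LocalConnectomeDB, factor: float = 0.6, n_bins: int = 256) -> float:
    """QA threshold for pool tractography: factor x Otsu over fiber-voxel QA."""
    qa = db.geometry.template_qa[db.geometry.n_dirs > 0]
    try:
        return factor * otsu_threshold(qa, n_bins=n_bins)
    except ValueError:  # all fiber voxels share one QA value
        return factor * float(qa.mean())


def run_pipeline(db: LocalConnectomeDB, config: RunConfig) -> RunReport:
    """Execute stages A-F on an in-memory database."""
    problems = validate_config(config)
    if problems:
        raise ValueError("invalid config: " + "; ".join(problems))
    report = RunReport(seed=config.seed)

    # A/B: database (+ optional outlier QC)
    if config.qc_outliers:
        db, qc = exclude_outlier_subjects(db, z_max=config.outlier_z_max)
        report.excluded_subjects = list(qc.excluded_subjects)
    report.n_subjects = len(db.active_subjects)
    report.n_features = db.geometry.n_features
    geometry = db.geometry

    # C: omnibus KW map and 0.6 x Otsu screen
    hmap = kw_map(db)
    report.h_otsu = otsu_threshold(hmap.values, n_bins=config.omnibus.n_bins)
    report.h_threshold = config.omnibus.factor * report.h_otsu
    passing, supra_vox = h_supra_mask(
        hmap, factor=config.omnibus.factor, n_bins=config.omnibus.n_bins
    )
    report.sdf_pass_fraction = float(passing.mean())
    report.n_supra_voxels = int(supra_vox.sum())

    # D: cluster correction, negation, pool tractography
    cluster_mask = cluster_filter(
        supra_vox,
        min_size=config.omnibus.min_cluster,
        connectivity=config.omnibus.connectivity,
    )
    from scipy import ndimage

    _, n_clusters = ndimage.label(cluster_mask, structure=np.ones((3, 3, 3), bool))
    report.n_clusters = int(n_clusters)
    report.n_cluster_voxels = int(cluster_mask.sum())
    brain_mask = np.ones(geometry.dims, dtype=bool)
    terminative = negate_mask(cluster_mask, brain_mask)

    report.qa_threshold = pool_qa_threshold(
        db, factor=config.omnibus.factor, n_bins=config.omnibus.n_bins
    )
    pool, pool_roi = build_track_pool(
        geometry,
        cluster_mask,
        terminative,
        qa_threshold=report.qa_threshold,
        angular_deg=config.tracking.angular_threshold_deg,
        n_seeds=config.tracking.n_seeds,
        seed=config.seed,
    )
    report.n_pool_tracks = len(pool)
    report.n_pool_voxels = int(pool_roi.sum())

    # F: post-hoc designs
    track_params = TrackingParams(
        qa_threshold=report.qa_threshold,
        angular_threshold_deg=config.tracking.angular_threshold_deg,
        step_size=config.tracking.step_size,
        min_length=config.tracking.min_length,
        max_length=config.tracking.max_length,
        n_seeds=config.tracking.n_seeds,
        seed=config.seed,
    )
    for design in config.designs:
        tmap = feature_t_map(db, design)
        for sign in ("+", "-"):
            grown = connectometry_tracks(tmap, sign, design, geometry, track_params)
            pruned = topology_informed_pruning(grown, geometry, rounds=design.tip_rounds)
            if config.constrain_by_pool and design.mode == "group_compare":
                constrained = filter_tracks_by_roi(
                    pruned, pool_roi, geometry, min_inside_frac=1.0, dilation_voxels=1
                )
            else:
                constrained = pruned
            fdr_table, findings = permutation_fdr(
                db, design, geometry, track_params, constrained, sign=sign
            )
            report.design_results.append(
                DesignResult(
                    design=design,
                    sign=sign,
                    n_tracks_grown=len(grown),
                    n_tracks_after_tip=len(pruned),
                    n_tracks_in_pool=len(constrained),
                    fdr_table=fdr_table,
                    findings=findings,
                )
            )
    return report
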