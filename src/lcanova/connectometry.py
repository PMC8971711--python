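"""Post-hoc connectometry: t-maps, track growing, pruning, permutation FDR.

Group and correlational connectometry share one statistic: the ordinary
least-squares t of an effect regressor (a two-group indicator or a continuous
score) on each feature's SDF values, with nuisance covariates partialled out.
Features whose t exceeds the design's t-threshold (with matching sign) form
the allowed set along which deterministic tracks are grown; tracks shorter
than the length threshold are dropped and the remainder pruned by
topology-informed pruning (TIP).  Significance is assessed by permuting the
effect regressor across subjects (nuisance fixed) and recomputing the track
count: FDR at candidate length L is the mean permuted count of tracks >= L
divided by the observed count, clipped to [0, 1].
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .connectome_db import FiberGeometry, LocalConnectomeDB
from .omnibus import StatisticMap
from .tracking import Tractogram, TrackingParams, tracks_to_roi, whole_brain_track


@dataclass
class DesignSpec:
    """What to test and how hard to screen it.

    ``contrast`` is a (group_a, group_b) pair in group_compare mode (positive
    t means a > b) or a score name in correlation mode.  Defaults follow the
    connectometry conventions this pipeline was built for: t-threshold 2.0
    for group comparisons and 2.5 for correlations, 40 mm length threshold,
    2 TIP rounds, 4000 permutations at FDR 0.05.
    """

    mode: str = "group_compare"
    contrast: tuple[str, str] | str = ("TC", "EPT")
    nuisance: tuple[str, ...] = ()
    t_threshold: float = 2.0
    length_threshold: float = 40.0
    n_permutations: int = 4000
    fdr_level: float = 0.05
    tip_rounds: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mode not in ("group_compare", "correlation"):
            raise ValueError("mode must be 'group_compare' or 'correlation'")
        if self.t_threshold <= 0:
            raise ValueError("t_threshold must be positive")
        if not (0 < self.fdr_level < 1):
            raise ValueError("fdr_level must be in (0, 1)")
        if self.n_permutations < 100:
            raise ValueError("need at least 100 permutations")


@dataclass
class Finding:
    """A surviving track bundle at the reporting length."""

    sign: str
    tracks: Tractogram
    roi: np.ndarray
    length_mm: float
    fdr: float
    per_length_counts: dict[float, int] = field(default_factory=dict)


# --------------------------------------------------------------------------
# Regression machinery
# --------------------------------------------------------------------------


def residualize(y: np.ndarray, covariates: np.ndarray | None) -> np.ndarray:
    """OLS residuals of y on an intercept plus covariate columns."""
    y = np.asarray(y, dtype=float)
    n = y.shape[0]
    if covariates is None or np.size(covariates) == 0:
        return y - y.mean()
    C = np.asarray(covariates, dtype=float)
    if C.ndim == 1:
        C = C[:, None]
    X = np.column_stack([np.ones(n), C])
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("rank deficient: collinear covariates")
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    return y - X @ beta


def _design_matrix(
    db: LocalConnectomeDB, design: DesignSpec
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Rows used, effect regressor, nuisance columns for the design."""
    labels = db.group_labels()
    if design.mode == "group_compare":
        a, b = design.contrast
        rows = np.flatnonzero((labels == a) | (labels == b))
        if rows.size == 0:
            raise ValueError(f"no subjects in groups {design.contrast}")
        effect = (labels[rows] == a).astype(float)
    else:
        rows = np.arange(len(labels))
        effect = db.score_vector(str(design.contrast))
    if design.nuisance:
        cols = [db.score_vector(name)[rows] for name in design.nuisance]
        nuisance = np.column_stack(cols)
    else:
        nuisance = np.zeros((rows.size, 0))
    return rows, effect, nuisance


def _t_statistics(
    Y: np.ndarray, effect: np.ndarray, nuisance: np.ndarray
) -> np.ndarray:
    """Vectorized OLS t of the effect column over feature columns of Y."""
    n = Y.shape[0]
    X = np.column_stack([np.ones(n), effect, nuisance])
    p = X.shape[1]
    if n - p < 3:
        raise ValueError("fewer than 3 residual degrees of freedom")
    XtX = X.T @ X
    XtX_inv = np.linalg.pinv(XtX)
    B = XtX_inv @ (X.T @ Y)  # (p, F)
    resid = Y - X @ B
    sigma2 = (resid**2).sum(axis=0) / (n - p)
    se = np.sqrt(np.maximum(sigma2 * XtX_inv[1, 1], 0.0))
    with np.errstate(invalid="ignore", divide="ignore"):
        t = np.where(se > 0, B[1] / np.where(se > 0, se, 1.0), 0.0)
    return t


def feature_t_map(db: LocalConnectomeDB, design: DesignSpec) -> StatisticMap:
    """Per-feature OLS t of the design's effect regressor (sign = direction)."""
    rows, effect, nuisance = _design_matrix(db, design)
    t = _t_statistics(db.matrix[rows], effect, nuisance)
    return StatisticMap(values=t, kind="t", geometry=db.geometry)


# --------------------------------------------------------------------------
# Track growing and pruning
# --------------------------------------------------------------------------


def connectometry_tracks(
    tmap: StatisticMap,
    sign: str,
    design: DesignSpec,
    geometry: FiberGeometry,
    params: TrackingParams,
) -> Tractogram:
    """Grow tracks along features whose t passes the signed threshold."""
    if tmap.kind != "t":
        raise ValueError("connectometry_tracks expects a t map")
    if sign == "+":
        allowed = tmap.values > design.t_threshold
    elif sign == "-":
        allowed = tmap.values < -design.t_threshold
    else:
        raise ValueError("sign must be '+' or '-'")
    if not allowed.any():
        return Tractogram([], params.resolved_step(geometry), {"sign": sign})
    local = TrackingParams(
        qa_threshold=params.qa_threshold,
        angular_threshold_deg=params.angular_threshold_deg,
        step_size=params.step_size,
        min_length=design.length_threshold,
        max_length=params.max_length,
        n_seeds=params.n_seeds,
        seed=params.seed,
    )
    tracks = whole_brain_track(
        geometry, geometry.template_qa, local, allowed_features=allowed
    )
    tracks.provenance["sign"] = sign
    return tracks


def topology_informed_pruning(
    tractogram: Tractogram,
    geometry: FiberGeometry,
    rounds: int = 2,
    density_frac: float = 0.2,
) -> Tractogram:
    """Iteratively drop streamlines crossing low-track-density voxels.

    Per round the per-voxel streamline count is computed; voxels with nonzero
    density below ``density_frac`` x mean nonzero density are noise voxels,
    and any streamline visiting one is removed.  Converged (and idempotent)
    once no voxel is marked.
    """
    from .tracking import streamline_voxels

    current = tractogram
    for _ in range(rounds):
        if len(current) == 0:
            break
        density = np.zeros(geometry.dims)
        visited = [streamline_voxels(s, geometry) for s in current.streamlines]
        for vox in visited:
            density[vox[:, 0], vox[:, 1], vox[:, 2]] += 1
        nz = density[density > 0]
        cutoff = density_frac * nz.mean()
        noise = (density > 0) & (density < cutoff)
        if not noise.any():
            break
        keep = [
            s
            for s, vox in zip(current.streamlines, visited)
            if not noise[vox[:, 0], vox[:, 1], vox[:, 2]].any()
        ]
        current = Tractogram(keep, current.step_size, dict(current.provenance))
    return current


# --------------------------------------------------------------------------
# Permutation FDR
# --------------------------------------------------------------------------


def _count_at_lengths(lengths: np.ndarray, candidates: np.ndarray) -> np.ndarray:
    return np.array([(lengths >= L).sum() for L in candidates], dtype=float)


def permutation_fdr(
    db: LocalConnectomeDB,
    design: DesignSpec,
    geometry: FiberGeometry,
    params: TrackingParams,
    observed: Tractogram,
    sign: str = "+",
    n_permutations: int | None = None,
) -> tuple[dict[float, float], list[Finding]]:
    """Permutation FDR over candidate track lengths; findings at the level.

    The effect regressor is shuffled across subjects (nuisance columns fixed)
    and the signed track count recomputed per permutation.  FDR(L) is the
    mean permuted count of tracks >= L over the observed count >= L, clipped
    to [0, 1]; the finding is the observed track set at the smallest L with
    FDR(L) <= the design's level.  Empty observed set -> FDR 1, no findings.
    """
    n_perm = n_permutations if n_permutations is not None else design.n_permutations
    obs_lengths = observed.lengths()
    if len(observed) == 0:
        return {design.length_threshold: 1.0}, []

    # candidate lengths: voxel-size steps from the length threshold up
    Lmax = float(obs_lengths.max())
    candidates = np.arange(design.length_threshold, Lmax + geometry.voxel_size, geometry.voxel_size)
    obs_counts = _count_at_lengths(obs_lengths, candidates)

    rows, effect, nuisance = _design_matrix(db, design)
    Y = db.matrix[rows]
    rng = np.random.default_rng(design.seed)
    perm_counts = np.zeros(len(candidates))
    for p in range(n_perm):
        shuffled = rng.permutation(effect)
        t = _t_statistics(Y, shuffled, nuisance)
        tmap = StatisticMap(values=t, kind="t", geometry=geometry)
        perm_params = TrackingParams(
            qa_threshold=params.qa_threshold,
            angular_threshold_deg=params.angular_threshold_deg,
            step_size=params.step_size,
            min_length=design.length_threshold,
            max_length=params.max_length,
            n_seeds=params.n_seeds,
            seed=params.seed,
        )
        tracks = connectometry_tracks(tmap, sign, design, geometry, perm_params)
        tracks = topology_informed_pruning(tracks, geometry, rounds=design.tip_rounds)
        perm_counts += _count_at_lengths(tracks.lengths(), candidates)
    perm_mean = perm_counts / n_perm

    with np.errstate(invalid="ignore", divide="ignore"):
        fdr = np.where(obs_counts > 0, perm_mean / np.maximum(obs_counts, 1e-300), 1.0)
    fdr = np.clip(fdr, 0.0, 1.0)
    fdr_table = {float(L): float(f) for L, f in zip(candidates, fdr)}

    findings: list[Finding] = []
    passing = np.flatnonzero(fdr <= design.fdr_level)
    if passing.size > 0:
        L = float(candidates[passing[0]])
        keep = [s for s in observed.streamlines if (len(s) - 1) * observed.step_size >= L]
        tg = Tractogram(keep, observed.step_size, dict(observed.provenance))
        findings.append(
            Finding(
                sign=sign,
                tracks=tg,
                roi=tracks_to_roi(tg, geometry),
                length_mm=L,
                fdr=float(fdr[passing[0]]),
                per_length_counts={
                    float(c): int(n) for c, n in zip(candidates, obs_counts)
                },
            )
        )
    return fdr_table, findings


# --------------------------------------------------------------------------
# Normalized QA and variance explained
# --------------------------------------------------------------------------


def normalize_qa(values: np.ndarray) -> np.ndarray:
    """Scale each subject's features by that subject's maximum (max -> 1)."""
    values = np.asarray(values, dtype=float)
    mx = values.max(axis=-1, keepdims=True)
    if np.any(mx <= 0):
        raise ValueError("subject with non-positive maximum cannot be normalized")
    return values / mx


def variance_explained(
    db: LocalConnectomeDB,
    roi: np.ndarray,
    score: str,
    nuisance: tuple[str, ...] = (),
    group: str | None = None,
) -> float:
    """R^2 of the (nuisance-residualized) score on mean normalized QA in the ROI.

    The predictor is each subject's mean normalized QA over all features whose
    voxel lies in the ROI.  ``group`` restricts to one study group.
    """
    roi = np.asarray(roi, dtype=bool)
    if not roi.any():
        raise ValueError("empty ROI")
    ijk, _, _ = db.geometry.feature_table()
    fmask = roi[ijk[:, 0], ijk[:, 1], ijk[:, 2]]
    if not fmask.any():
        raise ValueError("ROI contains no features")
    rows = np.arange(len(db.active_subjects))
    if group is not None:
        rows = np.flatnonzero(db.group_labels() == group)
    normed = normalize_qa(db.matrix[rows])
    x = normed[:, fmask].mean(axis=1)
    if x.std() == 0:
        raise ValueError("zero variance in predictor")
    y = db.score_vector(score)[rows]
    if nuisance:
        cov = np.column_stack([db.score_vector(n)[rows] for n in nuisance])
        y = residualize(y, cov)
    r = np.corrcoef(x, y)[0, 1]
    return float(r**2)


def language_composite(records) -> np.ndarray:
    """Mean of the PPVT4 and EVT2 standardized scores per subject."""
    out = []
    for rec in records:
        for key in ("ppvt4", "evt2"):
            if key not in rec.scores:
                raise ValueError(f"subject {rec.id!r} is missing score {key!r}")
        out.append((rec.scores["ppvt4"] + rec.scores["evt2"]) / 2.0)
    return np.asarray(out, dtype=float)
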