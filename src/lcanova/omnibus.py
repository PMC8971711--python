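"""Omnibus Kruskal-Wallis mapping and the statistically informed track pool.

The omnibus stage screens every (voxel, fiber-direction) feature with a
three-group Kruskal-Wallis test, thresholds the resulting H-statistic map at
0.6 x Otsu's threshold, applies a cluster extent correction (26-connectivity)
to the voxel projection, and converts the surviving clusters into a track
pool: the cluster mask's complement within the brain is used as a terminative
region for whole-volume tractography, tracks ending outside the clusters are
discarded, and the voxels visited by the survivors form the pool ROI that
later constrains post-hoc connectometry.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .connectome_db import FiberGeometry, LocalConnectomeDB
from .tracking import Tractogram, TrackingParams, tracks_to_roi, whole_brain_track


@dataclass
class StatisticMap:
    """Per-feature scalar statistic (H or t) bound to a geometry."""

    values: np.ndarray
    kind: str  # "H" or "t"
    geometry: FiberGeometry

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.kind not in ("H", "t"):
            raise ValueError("kind must be 'H' or 't'")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("statistic values must be finite")
        if self.kind == "H" and np.any(self.values < 0):
            raise ValueError("H statistics are non-negative")

    def to_voxel_max(self) -> np.ndarray:
        """Project to a voxel field by max over each voxel's directions."""
        out = np.zeros(self.geometry.dims)
        ijk, _, _ = self.geometry.feature_table()
        np.maximum.at(out, (ijk[:, 0], ijk[:, 1], ijk[:, 2]), self.values)
        return out


# --------------------------------------------------------------------------
# Kruskal-Wallis
# --------------------------------------------------------------------------


def kruskal_wallis_H(*groups: np.ndarray) -> float:
    """Kruskal-Wallis H with mid-ranks and tie correction.

    H = 12 / (N (N+1)) * sum_i n_i (Rbar_i - (N+1)/2)^2, divided by the tie
    correction 1 - sum(t^3 - t) / (N^3 - N).  Returns 0 when every pooled
    value ties (the correction denominator vanishes).
    """
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    arrays = [np.asarray(g, dtype=float).ravel() for g in groups]
    if any(a.size == 0 for a in arrays):
        raise ValueError("empty group")
    labels = np.concatenate(
        [np.full(a.size, i) for i, a in enumerate(arrays)]
    )
    pooled = np.concatenate(arrays)
    H = _kw_from_columns(pooled[:, None], labels)
    return float(H[0])


def _kw_from_columns(data: np.ndarray, labels: np.ndarray) -> np.ndarray:
    """Vectorized KW H over columns of ``data`` (N x F) for integer labels."""
    from scipy.stats import rankdata

    N, F = data.shape
    ranks = rankdata(data, axis=0)  # mid-ranks
    H = np.zeros(F)
    for g in np.unique(labels):
        sel = labels == g
        n = int(sel.sum())
        rbar = ranks[sel].mean(axis=0)
        H += n * (rbar - (N + 1) / 2) ** 2
    H *= 12.0 / (N * (N + 1))
    # tie correction per column: 1 - sum(t^3 - t) / (N^3 - N)
    svals = np.sort(data, axis=0)
    new_run = np.vstack([np.ones((1, F), bool), svals[1:] != svals[:-1]])
    run_id = np.cumsum(new_run, axis=0)  # run labels 1..R per column
    tie_term = np.zeros(F)
    for f in range(F):
        _, t = np.unique(run_id[:, f], return_counts=True)
        tie_term[f] = np.sum(t**3 - t)
    corr = 1.0 - tie_term / (N**3 - N)
    out = np.where(corr > 0, H / np.where(corr > 0, corr, 1.0), 0.0)
    return out


def kw_map(db: LocalConnectomeDB, group_labels: np.ndarray | None = None) -> StatisticMap:
    """Per-feature Kruskal-Wallis H map over the database's groups."""
    labels = np.asarray(group_labels) if group_labels is not None else db.group_labels()
    uniq, codes = np.unique(labels, return_inverse=True)
    if len(uniq) < 2:
        raise ValueError("need at least 2 groups")
    for g in uniq:
        if (labels == g).sum() < 2:
            raise ValueError(f"group {g!r} has fewer than 2 subjects")
    H = _kw_from_columns(db.matrix, codes)
    return StatisticMap(values=H, kind="H", geometry=db.geometry)


# --------------------------------------------------------------------------
# Otsu thresholding of the H map
# --------------------------------------------------------------------------


def otsu_threshold(values: np.ndarray, n_bins: int = 256) -> float:
    """Histogram threshold maximizing between-class variance.

    The histogram spans [min, max] with ``n_bins`` equal bins; candidate
    thresholds are the interior bin edges; ties break toward the lower
    threshold.  The returned value is the bin edge itself.
    """
    x = np.asarray(values, dtype=float).ravel()
    if x.size < 2 or x.min() == x.max():
        raise ValueError("degenerate histogram: need at least 2 distinct values")
    counts, edges = np.histogram(x, bins=n_bins, range=(x.min(), x.max()))
    centers = (edges[:-1] + edges[1:]) / 2
    w = counts.astype(float)
    total = w.sum()
    cum_w = np.cumsum(w)
    cum_m = np.cumsum(w * centers)
    mean_all = cum_m[-1] / total
    # split after bin b: class 0 = bins <= b, class 1 = rest
    w0 = cum_w[:-1] / total
    w1 = 1.0 - w0
    with np.errstate(invalid="ignore", divide="ignore"):
        mu0 = cum_m[:-1] / cum_w[:-1]
        mu1 = (cum_m[-1] - cum_m[:-1]) / (total - cum_w[:-1])
    sigma_b = np.where((w0 > 0) & (w1 > 0), w0 * w1 * (mu0 - mu1) ** 2, -np.inf)
    # ties (e.g. a plateau across empty bins) break toward the lower
    # threshold; a relative tolerance keeps the rule stable under float noise
    top = sigma_b.max()
    best = int(np.flatnonzero(sigma_b >= top - 1e-9 * abs(top))[0])
    return float(edges[best + 1])


def h_supra_mask(
    hmap: StatisticMap, factor: float = 0.6, n_bins: int = 256
) -> tuple[np.ndarray, np.ndarray]:
    """Features above factor x Otsu's threshold of the H map, and their voxels.

    A voxel enters the mask when at least one of its fiber directions passes.
    """
    if hmap.kind != "H":
        raise ValueError("h_supra_mask expects an H map")
    thr = factor * otsu_threshold(hmap.values, n_bins=n_bins)
    passing = hmap.values > thr
    geometry = hmap.geometry
    ijk, _, _ = geometry.feature_table()
    vox = np.zeros(geometry.dims, dtype=bool)
    sel = ijk[passing]
    vox[sel[:, 0], sel[:, 1], sel[:, 2]] = True
    return passing, vox


# --------------------------------------------------------------------------
# Cluster correction and mask algebra
# --------------------------------------------------------------------------

_STRUCT_26 = np.ones((3, 3, 3), dtype=bool)


def cluster_filter(
    mask: np.ndarray, min_size: int = 20, connectivity: int = 26
) -> np.ndarray:
    """Remove connected components smaller than ``min_size`` voxels.

    26-connectivity (faces, edges and corners) by default; 6 selects
    face-only adjacency.
    """
    mask = np.asarray(mask, dtype=bool)
    if connectivity == 26:
        struct = _STRUCT_26
    elif connectivity == 6:
        struct = ndimage.generate_binary_structure(3, 1)
    else:
        raise ValueError("connectivity must be 6 or 26")
    labels, n = ndimage.label(mask, structure=struct)
    if n == 0:
        return np.zeros_like(mask)
    sizes = np.bincount(labels.ravel())
    keep = sizes >= min_size
    keep[0] = False
    return keep[labels]


def negate_mask(cluster_mask: np.ndarray, brain_mask: np.ndarray) -> np.ndarray:
    """Complement of the cluster mask within the brain."""
    cluster_mask = np.asarray(cluster_mask, dtype=bool)
    brain_mask = np.asarray(brain_mask, dtype=bool)
    if np.any(cluster_mask & ~brain_mask):
        raise ValueError("cluster mask extends outside the brain mask")
    return brain_mask & ~cluster_mask


# --------------------------------------------------------------------------
# Track pool
# --------------------------------------------------------------------------


def build_track_pool(
    geometry: FiberGeometry,
    cluster_mask: np.ndarray,
    terminative_mask: np.ndarray,
    qa_threshold: float,
    angular_deg: float = 60.0,
    n_seeds: int = 100_000,
    seed: int = 0,
    min_length: float | None = None,
) -> tuple[Tractogram, np.ndarray]:
    """Whole-volume tracking terminated by the negated mask -> pool ROI.

    Tracks whose endpoints fall outside the cluster mask are discarded; the
    pool ROI is the set of voxels visited by the surviving tracks.
    """
    if qa_threshold <= 0:
        raise ValueError("qa_threshold must be positive")
    params = TrackingParams(
        qa_threshold=qa_threshold,
        angular_threshold_deg=angular_deg,
        n_seeds=n_seeds,
        seed=seed,
        min_length=min_length if min_length is not None else 2 * geometry.voxel_size,
    )
    pool = whole_brain_track(
        geometry, geometry.template_qa, params, terminative=terminative_mask
    )
    cluster_mask = np.asarray(cluster_mask, dtype=bool)
    dims = np.asarray(geometry.dims)
    keep = []
    for s in pool.streamlines:
        ends = np.floor(s[[0, -1]] / geometry.voxel_size).astype(int)
        np.clip(ends, 0, dims - 1, out=ends)
        if cluster_mask[ends[:, 0], ends[:, 1], ends[:, 2]].all():
            keep.append(s)
    survivors = Tractogram(keep, pool.step_size, dict(pool.provenance))
    roi = tracks_to_roi(survivors, geometry)
    return survivors, roi
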