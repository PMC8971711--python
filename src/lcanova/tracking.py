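"""Deterministic streamline tractography on discrete fiber geometry.

Euler propagation with a fixed step: at each step the voxel containing the
current point offers up to three candidate fiber directions; the candidate
closest in axial angle (|cosine|, directions are sign-free) to the incoming
direction is taken, with its sign chosen to keep the turn below the angular
threshold.  A streamline ends when no candidate is within the angular
threshold, the candidate's QA is at or below the QA threshold, the next point
would leave the volume, or the next voxel belongs to the terminative mask
(the step into a terminative voxel is never taken).

Propagation is batched: all seeds advance in lock-step through vectorized
numpy operations, which keeps whole-brain runs with 1e5 seeds fast enough for
permutation loops.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np

from .connectome_db import MAX_SLOTS, FiberGeometry


@dataclass
class TrackingParams:
    """Parameters of deterministic QA-guided tracking.

    ``step_size`` defaults to half the voxel edge when left None.
    """

    qa_threshold: float = 0.1
    angular_threshold_deg: float = 60.0
    step_size: float | None = None
    min_length: float = 10.0
    max_length: float = 400.0
    n_seeds: int = 100_000
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.angular_threshold_deg <= 90):
            raise ValueError("angular threshold must be in (0, 90] degrees")
        if self.min_length >= self.max_length:
            raise ValueError("min_length must be below max_length")
        if self.step_size is not None and self.step_size <= 0:
            raise ValueError("step_size must be positive")

    def resolved_step(self, geometry: FiberGeometry) -> float:
        step = self.step_size if self.step_size is not None else geometry.voxel_size / 2
        if step > geometry.voxel_size:
            raise ValueError("step_size must not exceed the voxel edge")
        return step


@dataclass
class Tractogram:
    """A list of streamlines (mm coordinates) with provenance."""

    streamlines: list[np.ndarray]
    step_size: float
    provenance: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.streamlines)

    def lengths(self) -> np.ndarray:
        return np.array(
            [(len(s) - 1) * self.step_size for s in self.streamlines], dtype=float
        )

    # -- I/O --------------------------------------------------------------

    def save(self, path: str | Path, geometry: FiberGeometry) -> None:
        """Write TRK or TCK (by extension) with a JSON provenance sidecar."""
        path = Path(path)
        affine = np.diag([geometry.voxel_size] * 3 + [1.0]).astype(float)
        header = {}
        if path.suffix == ".trk":
            header[nib.streamlines.trk.Field.VOXEL_SIZES] = (geometry.voxel_size,) * 3
            header[nib.streamlines.trk.Field.DIMENSIONS] = geometry.dims
            header[nib.streamlines.trk.Field.VOXEL_TO_RASMM] = affine
        tgram = nib.streamlines.Tractogram(
            [np.asarray(s, dtype=np.float32) for s in self.streamlines],
            affine_to_rasmm=np.eye(4),
        )
        nib.streamlines.save(tgram, str(path), header=header or None)
        sidecar = dict(self.provenance)
        sidecar["n_streamlines"] = len(self)
        sidecar["step_size"] = self.step_size
        path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar, indent=1))

    @classmethod
    def load(cls, path: str | Path, step_size: float) -> "Tractogram":
        tf = nib.streamlines.load(str(path))
        return cls(
            streamlines=[np.asarray(s, dtype=float) for s in tf.streamlines],
            step_size=step_size,
        )


def _padded_fields(
    geometry: FiberGeometry, allowed_features: np.ndarray | None
) -> tuple[np.ndarray, np.ndarray]:
    """Per-voxel candidate directions and usability flags.

    Returns ``dirs`` (nx, ny, nz, MAX_SLOTS, 3) with NaN padding and
    ``usable`` (nx, ny, nz, MAX_SLOTS) — slot exists, has QA support and, when
    given, belongs to the allowed feature set.
    """
    slots = np.arange(MAX_SLOTS)[None, None, None, :]
    usable = slots < geometry.n_dirs[..., None]
    if allowed_features is not None:
        grid = geometry.feature_grid_index()
        allowed_grid = np.zeros_like(usable)
        ok = grid >= 0
        allowed_grid[ok] = np.asarray(allowed_features, dtype=bool)[grid[ok]]
        usable &= allowed_grid
    return geometry.directions, usable


def _propagate_batch(
    seeds_mm: np.ndarray,
    init_dirs: np.ndarray,
    geometry: FiberGeometry,
    qa_field: np.ndarray,
    params: TrackingParams,
    terminative: np.ndarray | None,
    allowed_features: np.ndarray | None,
) -> list[np.ndarray]:
    """Advance all half-streamlines in lock-step; returns per-seed point lists.

    Each returned array starts at the seed point.  ``qa_field`` is per-voxel.
    """
    step = params.resolved_step(geometry)
    cos_thr = np.cos(np.deg2rad(params.angular_threshold_deg))
    dims = np.asarray(geometry.dims)
    bounds = dims * geometry.voxel_size
    dirs_grid, usable = _padded_fields(geometry, allowed_features)
    max_steps = int(np.ceil(params.max_length / step)) + 1

    n = len(seeds_mm)
    pos = np.asarray(seeds_mm, dtype=float).copy()
    inc = np.asarray(init_dirs, dtype=float).copy()
    active = np.ones(n, dtype=bool)
    traj = np.empty((n, max_steps + 1, 3))
    traj[:, 0] = pos
    counts = np.ones(n, dtype=int)

    for _ in range(max_steps):
        if not active.any():
            break
        idx = np.flatnonzero(active)
        vox = np.floor(pos[idx] / geometry.voxel_size).astype(int)
        np.clip(vox, 0, dims - 1, out=vox)
        cand = dirs_grid[vox[:, 0], vox[:, 1], vox[:, 2]]  # (m, slots, 3)
        ok = usable[vox[:, 0], vox[:, 1], vox[:, 2]]  # (m, slots)
        qa_here = qa_field[vox[:, 0], vox[:, 1], vox[:, 2]]  # (m,)

        cosines = np.einsum("msd,md->ms", np.nan_to_num(cand), inc[idx])
        abs_cos = np.where(ok, np.abs(cosines), -np.inf)
        best = np.argmax(abs_cos, axis=1)
        m = len(idx)
        best_cos = abs_cos[np.arange(m), best]
        new_dir = np.nan_to_num(cand[np.arange(m), best])
        # orient the axial candidate along the incoming direction
        sign = np.where(cosines[np.arange(m), best] >= 0, 1.0, -1.0)
        new_dir = new_dir * sign[:, None]

        proceed = (best_cos >= cos_thr) & (qa_here > params.qa_threshold)
        nxt = pos[idx] + step * new_dir
        inside = np.all((nxt >= 0) & (nxt < bounds), axis=1)
        proceed &= inside
        if terminative is not None:
            nvox = np.floor(nxt / geometry.voxel_size).astype(int)
            np.clip(nvox, 0, dims - 1, out=nvox)
            hits = terminative[nvox[:, 0], nvox[:, 1], nvox[:, 2]]
            proceed &= ~hits

        stopped = idx[~proceed]
        active[stopped] = False
        moving = idx[proceed]
        pos[moving] = nxt[proceed]
        inc[moving] = new_dir[proceed]
        traj[moving, counts[moving]] = nxt[proceed]
        counts[moving] += 1

    return [traj[i, : counts[i]].copy() for i in range(n)]


def propagate(
    seed_point: np.ndarray,
    init_direction: np.ndarray,
    geometry: FiberGeometry,
    qa_field: np.ndarray,
    params: TrackingParams,
    terminative: np.ndarray | None = None,
    allowed_features: np.ndarray | None = None,
) -> np.ndarray:
    """Single half-streamline from ``seed_point`` (mm) along ``init_direction``."""
    pts = _propagate_batch(
        np.asarray(seed_point, dtype=float)[None],
        np.asarray(init_direction, dtype=float)[None],
        geometry,
        qa_field,
        params,
        terminative,
        allowed_features,
    )
    return pts[0]


def _assemble_bidirectional(
    fwd: list[np.ndarray], bwd: list[np.ndarray]
) -> list[np.ndarray]:
    out = []
    for f, b in zip(fwd, bwd):
        out.append(np.concatenate([b[::-1][:-1], f]) if len(b) > 1 else f)
    return out


def track_from_seed(
    seed_point: np.ndarray,
    init_direction: np.ndarray,
    geometry: FiberGeometry,
    qa_field: np.ndarray,
    params: TrackingParams,
    terminative: np.ndarray | None = None,
    allowed_features: np.ndarray | None = None,
) -> np.ndarray | None:
    """Bidirectional streamline; None when outside the length window."""
    seed = np.asarray(seed_point, dtype=float)[None]
    d = np.asarray(init_direction, dtype=float)
    fwd = _propagate_batch(seed, d[None], geometry, qa_field, params, terminative, allowed_features)
    bwd = _propagate_batch(seed, -d[None], geometry, qa_field, params, terminative, allowed_features)
    full = _assemble_bidirectional(fwd, bwd)[0]
    step = params.resolved_step(geometry)
    length = (len(full) - 1) * step
    if length < params.min_length or length > params.max_length:
        return None
    return full


def _seed_points(
    geometry: FiberGeometry,
    qa_field: np.ndarray,
    params: TrackingParams,
    rng: np.random.Generator,
    seed_mask: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Uniform random seeds in voxels above the QA threshold (and mask)."""
    eligible = qa_field > params.qa_threshold
    if seed_mask is not None:
        eligible &= seed_mask
    vox = np.argwhere(eligible)
    if len(vox) == 0:
        return np.zeros((0, 3)), np.zeros((0, 3))
    pick = rng.integers(0, len(vox), size=params.n_seeds)
    offsets = rng.random((params.n_seeds, 3))
    pts = (vox[pick] + offsets) * geometry.voxel_size
    # initial direction: a random direction slot of the seed voxel
    v = vox[pick]
    n_avail = geometry.n_dirs[v[:, 0], v[:, 1], v[:, 2]].astype(int)
    slot = (rng.random(params.n_seeds) * n_avail).astype(int)
    dirs = geometry.directions[v[:, 0], v[:, 1], v[:, 2], slot]
    return pts, dirs


def whole_brain_track(
    geometry: FiberGeometry,
    qa_field: np.ndarray | None = None,
    params: TrackingParams | None = None,
    terminative: np.ndarray | None = None,
    allowed_features: np.ndarray | None = None,
    seed_mask: np.ndarray | None = None,
) -> Tractogram:
    """Whole-volume deterministic tracking from seeded random positions.

    Fully reproducible: the provenance records params and seed.  When
    ``allowed_features`` is given, seeds are restricted to voxels holding at
    least one allowed feature and propagation only follows allowed slots.
    """
    params = params or TrackingParams()
    if qa_field is None:
        qa_field = geometry.template_qa
    rng = np.random.default_rng(params.seed)
    if allowed_features is not None:
        ijk, _, _ = geometry.feature_table()
        amask = np.zeros(geometry.dims, dtype=bool)
        sel = ijk[np.asarray(allowed_features, dtype=bool)]
        amask[sel[:, 0], sel[:, 1], sel[:, 2]] = True
        seed_mask = amask if seed_mask is None else (seed_mask & amask)
    seeds, init_dirs = _seed_points(geometry, qa_field, params, rng, seed_mask)
    if len(seeds) == 0:
        return Tractogram([], params.resolved_step(geometry), {"seed": params.seed})

    step = params.resolved_step(geometry)
    keep: list[np.ndarray] = []
    chunk = 8192  # bounds the (chunk, max_steps, 3) trajectory buffer
    for lo in range(0, len(seeds), chunk):
        sl = slice(lo, lo + chunk)
        fwd = _propagate_batch(
            seeds[sl], init_dirs[sl], geometry, qa_field, params, terminative, allowed_features
        )
        bwd = _propagate_batch(
            seeds[sl], -init_dirs[sl], geometry, qa_field, params, terminative, allowed_features
        )
        for s in _assemble_bidirectional(fwd, bwd):
            if params.min_length <= (len(s) - 1) * step <= params.max_length:
                keep.append(s)
    return Tractogram(
        keep,
        step,
        provenance={
            "seed": params.seed,
            "n_seeds": params.n_seeds,
            "qa_threshold": params.qa_threshold,
            "angular_threshold_deg": params.angular_threshold_deg,
        },
    )


def streamline_voxels(s: np.ndarray, geometry: FiberGeometry) -> np.ndarray:
    """Unique voxel indices visited by a streamline's points."""
    vox = np.floor(np.asarray(s) / geometry.voxel_size).astype(int)
    np.clip(vox, 0, np.asarray(geometry.dims) - 1, out=vox)
    return np.unique(vox, axis=0)


def tracks_to_roi(tractogram: Tractogram, geometry: FiberGeometry) -> np.ndarray:
    """Voxel mask of all voxels containing at least one streamline point."""
    mask = np.zeros(geometry.dims, dtype=bool)
    for s in tractogram.streamlines:
        vox = streamline_voxels(s, geometry)
        mask[vox[:, 0], vox[:, 1], vox[:, 2]] = True
    return mask


def filter_tracks_by_roi(
    tractogram: Tractogram,
    roi: np.ndarray,
    geometry: FiberGeometry,
    min_inside_frac: float = 1.0,
    dilation_voxels: int = 1,
) -> Tractogram:
    """Keep streamlines whose point fraction inside the dilated ROI passes."""
    from scipy import ndimage

    roi = np.asarray(roi, dtype=bool)
    if dilation_voxels > 0:
        roi = ndimage.binary_dilation(
            roi, structure=np.ones((3, 3, 3), dtype=bool), iterations=dilation_voxels
        )
    keep = []
    dims = np.asarray(geometry.dims)
    for s in tractogram.streamlines:
        vox = np.floor(s / geometry.voxel_size).astype(int)
        np.clip(vox, 0, dims - 1, out=vox)
        inside = roi[vox[:, 0], vox[:, 1], vox[:, 2]]
        if inside.mean() >= min_inside_frac:
            keep.append(s)
    return Tractogram(keep, tractogram.step_size, dict(tractogram.provenance))
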