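"""Local-connectome database: fiber geometry, subject records, QC, template.

The local connectome of one subject is the vector of SDF (spin distribution
function) values sampled at every (voxel, fiber-direction) pair of a shared
template geometry.  Stacking subjects row-wise gives the connectometry
database matrix (subjects x features) on which all downstream statistics
operate.

Feature (column) ordering is a pure function of the geometry: voxels sorted by
linear index with the first axis (i) varying fastest, then direction slot
ascending within a voxel.  The ordering is arbitrary but fixed, documented and
round-trip tested.
"""

from __future__ import annotations

import dataclasses
import io
import json
import zipfile
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

MAX_SLOTS = 3  # at most 3 resolved fiber directions per voxel

STUDY_GROUPS = ("TC", "EPT", "EPT_HLD")


# --------------------------------------------------------------------------
# Domain types
# --------------------------------------------------------------------------


@dataclass
class FiberGeometry:
    """Template grid with per-voxel fiber directions and template QA.

    Parameters
    ----------
    dims : tuple of int
        Grid shape (nx, ny, nz) in voxels.
    voxel_size : float
        Isotropic voxel edge length in mm.  Voxel (i, j, k) has its center at
        ``(index + 0.5) * voxel_size`` mm; volume bounds are half-open.
    directions : ndarray, shape (nx, ny, nz, MAX_SLOTS, 3)
        Unit fiber directions, NaN-padded beyond ``n_dirs``.  Directions are
        axial (sign-free): v and -v describe the same fiber.
    n_dirs : ndarray, shape (nx, ny, nz), uint8
        Number of fiber directions resolved in each voxel (0..3).
    template_qa : ndarray, shape (nx, ny, nz)
        Non-negative template anisotropy; exactly 0 in voxels with no fibers.
    slot_qa : ndarray, shape (nx, ny, nz, MAX_SLOTS), optional
        Per-direction template SDF amplitude (the feature-wise template).
    """

    dims: tuple[int, int, int]
    voxel_size: float
    directions: np.ndarray
    n_dirs: np.ndarray
    template_qa: np.ndarray
    slot_qa: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.dims = tuple(int(d) for d in self.dims)
        self.n_dirs = np.asarray(self.n_dirs, dtype=np.uint8)
        self.directions = np.asarray(self.directions, dtype=float)
        self.template_qa = np.asarray(self.template_qa, dtype=float)
        if self.directions.shape != (*self.dims, MAX_SLOTS, 3):
            raise ValueError("directions shape does not match dims")
        if self.n_dirs.shape != self.dims or self.template_qa.shape != self.dims:
            raise ValueError("per-voxel field shape does not match dims")
        if np.any(self.template_qa < 0):
            raise ValueError("template_qa must be non-negative")
        if np.any(self.template_qa[self.n_dirs == 0] != 0):
            raise ValueError("voxels without fiber directions must have template_qa = 0")
        slot = np.arange(MAX_SLOTS)[None, None, None, :]
        present = slot < self.n_dirs[..., None]
        norms = np.linalg.norm(self.directions, axis=-1)
        if present.any() and not np.allclose(norms[present], 1.0, atol=1e-9):
            raise ValueError("fiber directions must be unit vectors")

    @property
    def n_features(self) -> int:
        return int(self.n_dirs.sum())

    def feature_table(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Canonical feature index.

        Returns
        -------
        ijk : ndarray (F, 3) int
            Voxel indices per feature.
        slot : ndarray (F,) int
            Direction slot per feature.
        vec : ndarray (F, 3)
            Unit direction per feature.
        """
        nx, ny, nz = self.dims
        present = np.arange(MAX_SLOTS)[None, None, None, :] < self.n_dirs[..., None]
        # C-order over (k, j, i, slot) sorts by voxel linear index with i
        # fastest, then slot -- the documented column order.
        idx = np.argwhere(present.transpose(2, 1, 0, 3))
        kk, jj, ii, slot = idx.T
        ijk = np.stack([ii, jj, kk], axis=1)
        vec = self.directions[ii, jj, kk, slot]
        return ijk, slot, vec

    def feature_linear_voxel(self) -> np.ndarray:
        """Linear voxel index (i fastest) of each feature."""
        ijk, _, _ = self.feature_table()
        nx, ny, _ = self.dims
        return ijk[:, 0] + nx * (ijk[:, 1] + ny * ijk[:, 2])

    def feature_grid_index(self) -> np.ndarray:
        """Map (nx, ny, nz, MAX_SLOTS) -> feature column, -1 where absent."""
        grid = np.full((*self.dims, MAX_SLOTS), -1, dtype=np.int64)
        ijk, slot, _ = self.feature_table()
        grid[ijk[:, 0], ijk[:, 1], ijk[:, 2], slot] = np.arange(len(slot))
        return grid


@dataclass
class SubjectRecord:
    """One participant: group label, behavioral scores, exclusion state."""

    id: str
    group: str
    scores: dict[str, float] = field(default_factory=dict)
    excluded: bool = False
    exclusion_reason: str = ""

    def __post_init__(self) -> None:
        if self.group not in STUDY_GROUPS:
            raise ValueError(
                f"unknown group {self.group!r}; expected one of {STUDY_GROUPS}"
            )


@dataclass
class LocalConnectomeDB:
    """Subjects x features SDF matrix bound to a fiber geometry."""

    matrix: np.ndarray
    subjects: list[SubjectRecord]
    geometry: FiberGeometry

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        n_active = sum(not s.excluded for s in self.subjects)
        if self.matrix.shape != (n_active, self.geometry.n_features):
            raise ValueError(
                f"matrix shape {self.matrix.shape} does not match "
                f"{n_active} active subjects x {self.geometry.n_features} features"
            )
        if np.any(self.matrix < 0):
            raise ValueError("SDF values must be non-negative")

    @property
    def active_subjects(self) -> list[SubjectRecord]:
        return [s for s in self.subjects if not s.excluded]

    def group_labels(self) -> np.ndarray:
        return np.array([s.group for s in self.active_subjects])

    def score_vector(self, name: str) -> np.ndarray:
        vals = []
        for s in self.active_subjects:
            if name not in s.scores:
                raise KeyError(f"subject {s.id!r} is missing score {name!r}")
            vals.append(s.scores[name])
        return np.asarray(vals, dtype=float)

    # -- serialization ----------------------------------------------------

    def save(self, path: str | Path) -> None:
        """Write the database as a single zip archive (lossless round trip)."""
        path = Path(path)
        ijk, slot, vec = self.geometry.feature_table()
        buf = io.BytesIO()
        np.savez(
            buf,
            matrix=self.matrix,
            feature_ijk=ijk,
            feature_slot=slot,
            feature_dir=vec,
            directions=self.geometry.directions,
            n_dirs=self.geometry.n_dirs,
            template_qa=self.geometry.template_qa,
            slot_qa=(
                self.geometry.slot_qa
                if self.geometry.slot_qa is not None
                else np.zeros(0)
            ),
            dims=np.asarray(self.geometry.dims),
            voxel_size=np.asarray(self.geometry.voxel_size),
        )
        subjects = [dataclasses.asdict(s) for s in self.subjects]
        with zipfile.ZipFile(path, "w", compression=zipfile.ZIP_DEFLATED) as zf:
            zf.writestr("arrays.npz", buf.getvalue())
            zf.writestr("subjects.json", json.dumps(subjects, indent=1))

    @classmethod
    def load(cls, path: str | Path) -> "LocalConnectomeDB":
        with zipfile.ZipFile(Path(path)) as zf:
            with zf.open("arrays.npz") as f:
                arrays = np.load(io.BytesIO(f.read()))
            subjects = json.loads(zf.read("subjects.json"))
        slot_qa = arrays["slot_qa"]
        geom = FiberGeometry(
            dims=tuple(arrays["dims"].tolist()),
            voxel_size=float(arrays["voxel_size"]),
            directions=arrays["directions"],
            n_dirs=arrays["n_dirs"],
            template_qa=arrays["template_qa"],
            slot_qa=slot_qa if slot_qa.size else None,
        )
        records = [SubjectRecord(**s) for s in subjects]
        return cls(matrix=arrays["matrix"], subjects=records, geometry=geom)


@dataclass
class QCReport:
    """Quality-control outcomes for a cohort."""

    removed_volumes: dict[str, list[int]] = field(default_factory=dict)
    fraction_removed: dict[str, float] = field(default_factory=dict)
    spatial_correlation: dict[str, float] = field(default_factory=dict)
    mean_sdf_zscore: dict[str, float] = field(default_factory=dict)
    excluded_subjects: list[str] = field(default_factory=list)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=1))


# --------------------------------------------------------------------------
# Operations
# --------------------------------------------------------------------------


def neighboring_correlation_qc(
    dwi_stack: np.ndarray,
    gradient_dirs: np.ndarray,
    brain_mask: np.ndarray,
    corr_min: float = 0.9,
    max_removed_frac: float = 0.10,
) -> tuple[np.ndarray, bool]:
    """Volume-level QC by correlation with the nearest q-space neighbor.

    Each diffusion-weighted volume is correlated (Pearson, over brain-mask
    voxels) with the volume whose gradient direction is angularly closest
    (axial angle, since diffusion encoding is sign-free).  Volumes with a
    neighbor correlation below ``corr_min`` are dropped; the subject fails QC
    when more than ``max_removed_frac`` of volumes were dropped.

    Returns
    -------
    kept : ndarray of int
        Indices of retained volumes.
    passed : bool
        False iff the dropped fraction exceeds ``max_removed_frac``.
    """
    stack = np.asarray(dwi_stack, dtype=float)
    bvecs = np.asarray(gradient_dirs, dtype=float)
    mask = np.asarray(brain_mask, dtype=bool)
    n_vol = stack.shape[-1]
    if n_vol < 2:
        raise ValueError("insufficient volumes: need at least 2 diffusion volumes")
    if not mask.any():
        raise ValueError("brain mask is empty")
    if bvecs.shape != (n_vol, 3):
        raise ValueError("gradient directions must be (n_volumes, 3)")

    data = stack[mask, :]  # (n_mask_voxels, n_vol)
    # axial angle: |cos| large = close
    abs_cos = np.abs(bvecs @ bvecs.T)
    np.fill_diagonal(abs_cos, -np.inf)
    neighbor = np.argmax(abs_cos, axis=1)

    corrs = np.empty(n_vol)
    for v in range(n_vol):
        a = data[:, v]
        b = data[:, neighbor[v]]
        sa, sb = a.std(), b.std()
        if sa == 0 or sb == 0:
            corrs[v] = 0.0
        else:
            corrs[v] = float(np.corrcoef(a, b)[0, 1])
    keep = corrs >= corr_min
    kept = np.flatnonzero(keep)
    frac_removed = 1.0 - keep.mean()
    return kept, bool(frac_removed <= max_removed_frac)


def build_database(
    subject_values: np.ndarray,
    subjects: list[SubjectRecord],
    geometry: FiberGeometry,
) -> LocalConnectomeDB:
    """Assemble the subjects x features matrix in canonical column order.

    ``subject_values`` is (n_subjects, F) with columns already in canonical
    feature order, or (n_subjects, nx, ny, nz, MAX_SLOTS) volumes from which
    the canonical columns are extracted (shuffle-proof path).
    """
    values = np.asarray(subject_values, dtype=float)
    if len(subjects) < 2:
        raise ValueError("need at least 2 subjects")
    if values.ndim == 5:
        if values.shape[1:] != (*geometry.dims, MAX_SLOTS):
            raise ValueError("subject volumes do not match geometry dims")
        ijk, slot, _ = geometry.feature_table()
        matrix = values[:, ijk[:, 0], ijk[:, 1], ijk[:, 2], slot]
    elif values.ndim == 2:
        if values.shape[1] != geometry.n_features:
            # locate the first voxel whose slot count the input cannot cover
            ijk, slot, _ = geometry.feature_table()
            bad = ijk[min(values.shape[1], len(slot) - 1)]
            raise ValueError(
                f"feature count mismatch: got {values.shape[1]}, geometry has "
                f"{geometry.n_features}; first offending voxel {tuple(bad)}"
            )
        matrix = values
    else:
        raise ValueError("subject_values must be (S, F) or (S, nx, ny, nz, slots)")
    if values.shape[0] != len(subjects):
        raise ValueError("row count does not match subject list")
    return LocalConnectomeDB(matrix=matrix, subjects=list(subjects), geometry=geometry)


def make_template(
    subject_values: np.ndarray,
    groups: np.ndarray,
    fraction: float = 0.5,
    rng: np.random.Generator | int | None = None,
) -> tuple[np.ndarray, dict[str, list[int]]]:
    """Average a seeded per-group subject subset into a study template.

    An equal proportion (``fraction``, rounded up) of subjects is drawn from
    each group and their feature vectors are averaged.  Returns the template
    feature vector and the per-group selected row indices (the run log).
    """
    values = np.asarray(subject_values, dtype=float)
    groups = np.asarray(groups)
    if groups.size == 0:
        raise ValueError("empty group list")
    rng = np.random.default_rng(rng)
    selected: dict[str, list[int]] = {}
    rows: list[int] = []
    for g in np.unique(groups):
        members = np.flatnonzero(groups == g)
        if members.size == 0:
            raise ValueError(f"group {g!r} is empty")
        k = int(np.ceil(fraction * members.size))
        chosen = np.sort(rng.choice(members, size=k, replace=False))
        selected[str(g)] = chosen.tolist()
        rows.extend(chosen.tolist())
    template = values[rows].mean(axis=0)
    return template, selected


def registration_quality(
    subject_features: np.ndarray, template_features: np.ndarray
) -> float:
    """Spatial (Pearson) correlation between a subject and the template."""
    a = np.asarray(subject_features, dtype=float).ravel()
    b = np.asarray(template_features, dtype=float).ravel()
    if a.shape != b.shape:
        raise ValueError("feature counts differ")
    if a.std() == 0 or b.std() == 0:
        raise ValueError("degenerate input: zero variance")
    return float(np.corrcoef(a, b)[0, 1])


def exclude_outlier_subjects(
    db: LocalConnectomeDB, z_max: float = 2.0
) -> tuple[LocalConnectomeDB, QCReport]:
    """Drop subjects whose normalized mean SDF is a high outlier in their group.

    Each subject's features are divided by that subject's maximum (the
    "normalized" SDF), and the subject mean of these is compared, leave-one-out
    within the subject's group, to the rest of the group: excluded iff
    value > mean(rest) + z_max * sd(rest).  One-sided (high side only); a
    zero-variance rest-of-group never excludes.
    """
    active = db.active_subjects
    if len(active) < 3:
        raise ValueError("need at least 3 subjects for outlier screening")
    row_max = db.matrix.max(axis=1)
    if np.any(row_max <= 0):
        raise ValueError("subject with all-zero SDF cannot be normalized")
    norm_mean = (db.matrix / row_max[:, None]).mean(axis=1)
    groups = db.group_labels()

    report = QCReport()
    keep = np.ones(len(active), dtype=bool)
    for s_idx, rec in enumerate(active):
        rest = norm_mean[(groups == rec.group) & (np.arange(len(active)) != s_idx)]
        if rest.size < 2:
            z = 0.0
        else:
            sd = rest.std(ddof=1)
            z = 0.0 if sd == 0 else float((norm_mean[s_idx] - rest.mean()) / sd)
        report.mean_sdf_zscore[rec.id] = z
        if z > z_max:
            keep[s_idx] = False
            report.excluded_subjects.append(rec.id)

    new_subjects: list[SubjectRecord] = []
    for s in db.subjects:
        rec = dataclasses.replace(s)
        if not rec.excluded and rec.id in report.excluded_subjects:
            rec.excluded = True
            rec.exclusion_reason = f"normalized mean SDF > {z_max} SD above group"
        new_subjects.append(rec)
    filtered = LocalConnectomeDB(
        matrix=db.matrix[keep], subjects=new_subjects, geometry=db.geometry
    )
    return filtered, report
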