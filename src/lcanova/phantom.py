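"""Synthetic fiber phantoms and cohorts with planted group effects.

The generator emulates the data the pipeline consumes — per-subject SDF
values on a template fiber geometry — not raw diffusion signal.  A phantom is
a set of straight cylindrical bundles on a voxel grid; voxels inside a bundle
carry the bundle tangent as a unit fiber direction (up to 3 where bundles
cross).  Cohorts are three groups (term comparison TC, extremely-preterm EPT,
and EPT with history of language delay EPT_HLD) whose SDF values are the
template scaled by a planted regional group effect plus truncated Gaussian
noise, together with behavioral scores (a language composite built from PPVT4
and EVT2, and a WNV general-ability nuisance score) optionally coupled to the
planted region.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .connectome_db import (
    MAX_SLOTS,
    FiberGeometry,
    LocalConnectomeDB,
    SubjectRecord,
    build_database,
)


@dataclass
class Bundle:
    """Straight cylindrical fiber bundle in voxel coordinates.

    ``start``/``end`` are voxel-index coordinates of the axis endpoints
    (voxel centers are at index + 0.5); ``radius`` is in voxels.
    """

    start: tuple[float, float, float]
    end: tuple[float, float, float]
    radius: float = 2.0
    sdf: float = 0.6

    @property
    def direction(self) -> np.ndarray:
        d = np.asarray(self.end, dtype=float) - np.asarray(self.start, dtype=float)
        n = np.linalg.norm(d)
        if n == 0:
            raise ValueError("bundle has zero extent")
        return d / n

    def member_voxels(self, dims: tuple[int, int, int]) -> np.ndarray:
        """Boolean mask of voxels whose center lies inside the cylinder."""
        grid = np.stack(
            np.meshgrid(*[np.arange(n) + 0.5 for n in dims], indexing="ij"), axis=-1
        )
        a = np.asarray(self.start, dtype=float)
        d = self.direction
        length = float(np.linalg.norm(np.asarray(self.end) - a))
        rel = grid - a
        t = rel @ d
        perp = rel - t[..., None] * d
        dist = np.linalg.norm(perp, axis=-1)
        return (dist <= self.radius) & (t >= 0) & (t <= length)


@dataclass
class PhantomSpec:
    """Geometry of a synthetic phantom.

    Defaults: a 40x40x40 grid of 2 mm voxels with two orthogonal bundles of
    radius 2 voxels that cross at the volume center — small enough for
    desk-scale permutation runs while exhibiting a genuine crossing region.
    """

    dims: tuple[int, int, int] = (40, 40, 40)
    voxel_size: float = 2.0
    bundles: list[Bundle] = field(default_factory=list)
    background: float = 0.1

    def __post_init__(self) -> None:
        if not self.bundles:
            self.bundles = default_bundles(self.dims)
        if self.background <= 0:
            raise ValueError("background SDF level must be positive")
        for b in self.bundles:
            if b.sdf <= self.background:
                raise ValueError("bundle SDF must exceed the background level")


def default_bundles(dims: tuple[int, int, int]) -> list[Bundle]:
    nx, ny, nz = dims
    cz = nz / 2
    return [
        Bundle(start=(0.0, ny / 2, cz), end=(float(nx), ny / 2, cz), radius=2.0, sdf=0.6),
        Bundle(start=(nx / 2, 0.0, cz), end=(nx / 2, float(ny), cz), radius=2.0, sdf=0.5),
    ]


@dataclass
class EffectSpec:
    """A planted regional group effect plus a score model.

    ``segment`` restricts the effect to the part of the bundle whose axial
    coordinate t (voxels from the bundle start) lies in [t0, t1].
    ``frac_change`` scales in-region SDF by (1 + frac_change) for the affected
    groups.  The score model generates the language composite as
    intercept + slope * (subject in-region mean SDF) + N(0, noise_sd), either
    per group or shared.
    """

    bundle: int = 0
    segment: tuple[float, float] = (8.0, 32.0)
    groups: tuple[str, ...] = ("EPT",)
    frac_change: float = 0.20
    score_intercept: float = 100.0
    score_slope: float = 0.0
    score_noise_sd: float = 15.0
    target_r2: float | None = None

    def __post_init__(self) -> None:
        if abs(self.frac_change) >= 1:
            raise ValueError("|fractional change| must be < 1")
        if self.score_noise_sd < 0:
            raise ValueError("score noise SD must be non-negative")


def make_phantom(spec: PhantomSpec) -> FiberGeometry:
    """Rasterize the bundles into a fiber geometry.

    Each bundle voxel carries the bundle tangent as one direction slot;
    crossing voxels one slot per bundle (error above 3).  Per-slot template
    SDF equals the bundle amplitude; per-voxel template QA is the max over
    slots and exactly 0 outside all bundles.
    """
    dims = spec.dims
    directions = np.full((*dims, MAX_SLOTS, 3), np.nan)
    slot_qa = np.zeros((*dims, MAX_SLOTS))
    n_dirs = np.zeros(dims, dtype=np.uint8)
    for b in spec.bundles:
        mask = b.member_voxels(dims)
        if np.any(n_dirs[mask] >= MAX_SLOTS):
            raise ValueError("more than 3 bundles overlap a voxel")
        slots = n_dirs[mask]
        ii, jj, kk = np.nonzero(mask)
        directions[ii, jj, kk, slots] = b.direction
        slot_qa[ii, jj, kk, slots] = b.sdf
        n_dirs[mask] += 1
    template_qa = slot_qa.max(axis=-1)
    return FiberGeometry(
        dims=dims,
        voxel_size=spec.voxel_size,
        directions=directions,
        n_dirs=n_dirs,
        template_qa=template_qa,
        slot_qa=slot_qa,
    )


def effect_feature_mask(
    geometry: FiberGeometry, spec: PhantomSpec, effect: EffectSpec
) -> np.ndarray:
    """Boolean (F,) mask of features inside the planted segment."""
    b = spec.bundles[effect.bundle]
    ijk, slot, vec = geometry.feature_table()
    centers = ijk + 0.5
    a = np.asarray(b.start, dtype=float)
    d = b.direction
    length = float(np.linalg.norm(np.asarray(b.end) - a))
    rel = centers - a
    t = rel @ d
    perp = np.linalg.norm(rel - t[:, None] * d, axis=1)
    in_cyl = (perp <= b.radius) & (t >= 0) & (t <= length)
    in_seg = (t >= effect.segment[0]) & (t <= effect.segment[1])
    same_dir = np.abs(vec @ d) > 1 - 1e-9  # the slot belonging to this bundle
    return in_cyl & in_seg & same_dir


def effect_voxel_mask(
    geometry: FiberGeometry, spec: PhantomSpec, effect: EffectSpec
) -> np.ndarray:
    """Voxel projection of the planted feature mask."""
    fmask = effect_feature_mask(geometry, spec, effect)
    ijk, _, _ = geometry.feature_table()
    out = np.zeros(geometry.dims, dtype=bool)
    sel = ijk[fmask]
    out[sel[:, 0], sel[:, 1], sel[:, 2]] = True
    return out


DEFAULT_N_PER_GROUP = (28, 16, 8)  # TC, EPT, EPT_HLD
DEFAULT_NOISE_SD = 0.08  # with a +20% effect on SDF 0.6 this gives d ~ 1.5


def simulate_cohort(
    geometry: FiberGeometry,
    spec: PhantomSpec,
    effect: EffectSpec | None,
    n_per_group: tuple[int, int, int] = DEFAULT_N_PER_GROUP,
    noise_sd: float = DEFAULT_NOISE_SD,
    rng: np.random.Generator | int | None = None,
) -> tuple[LocalConnectomeDB, np.ndarray]:
    """Simulate a three-group cohort on the phantom.

    Per-feature value = template SDF x (1 + effect, when the subject's group
    is affected and the feature is in the planted region) + N(0, noise_sd),
    truncated at 0 to keep SDF non-negative.  Behavioral scores: the language
    composite follows the effect's score model (split symmetrically into PPVT4
    and EVT2 so their mean reproduces it exactly), WNV is an independent
    N(100, 15) nuisance.

    Returns the database and the planted ground-truth feature mask
    (all-False when ``effect`` is None).
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    if any(n < 2 for n in n_per_group):
        raise ValueError("need at least 2 subjects per group")
    rng = np.random.default_rng(rng)
    if geometry.slot_qa is None:
        raise ValueError("geometry carries no per-slot template SDF")

    ijk, slot, _ = geometry.feature_table()
    template = geometry.slot_qa[ijk[:, 0], ijk[:, 1], ijk[:, 2], slot]
    F = template.size

    if effect is not None:
        fmask = effect_feature_mask(geometry, spec, effect)
    else:
        fmask = np.zeros(F, dtype=bool)

    groups = ["TC", "EPT", "EPT_HLD"]
    records: list[SubjectRecord] = []
    rows: list[np.ndarray] = []
    region_means: list[float] = []
    for g, n in zip(groups, n_per_group):
        affected = effect is not None and g in effect.groups
        for s in range(n):
            mean = template.copy()
            if affected:
                mean[fmask] *= 1.0 + effect.frac_change
            vals = np.maximum(mean + rng.normal(0.0, noise_sd, size=F), 0.0)
            rows.append(vals)
            # score model couples to the normalized (subject-max-scaled)
            # region mean -- the quantity the variance-explained analysis uses
            region_means.append(
                float(vals[fmask].mean() / vals.max()) if fmask.any() else 0.0
            )
            records.append(SubjectRecord(id=f"{g}_{s:03d}", group=g))

    matrix = np.stack(rows)
    x = np.asarray(region_means)

    # behavioral scores
    if effect is not None and fmask.any():
        slope, noise = effect.score_slope, effect.score_noise_sd
        if effect.target_r2 is not None:
            # calibrate slope/noise so signal variance / total variance hits
            # the requested R^2 for the realized predictor spread
            slope = 100.0
            sig_var = np.var(slope * x)
            noise = float(
                np.sqrt(sig_var * (1.0 - effect.target_r2) / effect.target_r2)
            )
        composite = effect.score_intercept + slope * (x - x.mean()) + rng.normal(
            0.0, noise, size=len(records)
        )
    else:
        composite = 100.0 + rng.normal(0.0, 15.0, size=len(records))
    spread = rng.normal(0.0, 5.0, size=len(records))
    wnv = 100.0 + rng.normal(0.0, 15.0, size=len(records))
    for i, rec in enumerate(records):
        rec.scores = {
            "ppvt4": float(composite[i] + spread[i]),
            "evt2": float(composite[i] - spread[i]),
            "wnv": float(wnv[i]),
        }

    db = build_database(matrix, records, geometry)
    return db, fmask


def null_cohort(
    geometry: FiberGeometry,
    spec: PhantomSpec,
    n_per_group: tuple[int, int, int] = DEFAULT_N_PER_GROUP,
    noise_sd: float = DEFAULT_NOISE_SD,
    rng: np.random.Generator | int | None = None,
) -> LocalConnectomeDB:
    """Cohort with no planted effect: group labels carry no information."""
    db, _ = simulate_cohort(
        geometry, spec, effect=None, n_per_group=n_per_group, noise_sd=noise_sd, rng=rng
    )
    return db
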