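# Methods

This note documents the statistical model, the numerical choices, and what
the synthetic phantoms do and do not establish about behavior on real data.

## Data model

A **fiber geometry** is a template voxel grid (isotropic voxels, voxel center
at (index + 0.5) × voxel size mm, half-open bounds) carrying 0–3 unit fiber
directions per voxel. Directions are axial (sign-free): v and −v denote the
same fiber population, so all angular comparisons use |cos θ|. A **feature**
is one (voxel, direction slot) pair; columns of the database matrix are
ordered by voxel linear index with the first grid axis varying fastest, then
slot — any fixed bijection would do, this one is documented and round-trip
tested. Voxels with no fiber direction have template QA exactly 0; they can
never seed or sustain a streamline.

## Quality control

*Volume QC.* Each diffusion volume is Pearson-correlated (within the brain
mask) against the volume with the smallest axial angle between gradient
directions; volumes below 0.9 are dropped and a subject fails QC when more
than 10% of volumes are dropped. Note a corrupted volume also degrades the
correlation of any volume whose nearest neighbor it is — such collateral
removals are correct behavior, not a defect.

*Subject outliers.* Each subject's features are divided by that subject's
maximum ("normalized" SDF; the normalization makes subjects with different
global SDF scales comparable) and the subject mean of these is screened
leave-one-out within the subject's group: excluded iff it exceeds the rest's
mean by more than 2 of the rest's standard deviations, high side only.
**Caveat:** this rule is not idempotent in general — for a homogeneous group
of ~28 subjects the largest leave-one-out z often exceeds 2 by chance, so a
second pass may flag a new subject. The pipeline applies a single pass, which
is also the only defensible reading of a one-shot screening step.

*Template.* A seeded random 50% subset of each group is averaged feature-wise;
the selection is recorded in the run log. Registration quality is the Pearson
correlation of a subject's features with the template's.

## Omnibus screen

The Kruskal–Wallis H uses mid-ranks and the tie correction
1 − Σ(t³−t)/(N³−N); a fully tied feature returns H = 0 (the correction
denominator vanishes and there is genuinely no evidence either way). The
vectorized map implementation is checked against `scipy.stats.kruskal` to
1e-10 in tests but does not call it.

Otsu's threshold is computed on a 256-bin histogram over the observed range;
candidate thresholds are interior bin edges and the returned value is the
edge itself. Plateaus of the between-class variance (empty bins between
modes) are exact ties and resolve to the *lowest* edge, with a 1e-9 relative
tolerance so floating-point accumulation order cannot flip the choice. The
screen keeps features with H strictly above 0.6 × the threshold.

Because Otsu adapts to each H distribution, the *overall* pass fraction is
not a signal measure: a pure-noise H map passes a larger fraction (~0.41 on
the default phantom) than a planted-effect map (~0.33), since the signal
cluster pulls the threshold up. What distinguishes signal is enrichment of
passing features inside the affected region, which is what the tests assert.

Thresholded features project to voxels by "any direction passes"; clustering
then operates on voxels with 26-connectivity (faces, edges, corners) and an
extent threshold of 20 voxels. At 2 mm voxels this equals a 40 mm extent,
matching the track-length threshold; the minimum is configurable.

## Tractography

Deterministic Euler propagation with step = half the voxel edge (configurable,
never above one edge). At each step the current voxel's candidate directions
(optionally restricted to an allowed feature set) are compared to the
incoming direction by |cos θ|; the best candidate is taken, sign-aligned with
the incoming direction, provided the turn is within the 60° angular threshold
and the voxel's QA exceeds the QA threshold. A streamline ends when no
candidate qualifies, the next point would leave the volume, or the next voxel
is terminative — the step into a terminative voxel is never taken, so no
recorded point lies inside the terminative region. Nearest-voxel direction
lookup is used rather than interpolation: the geometry stores discrete axial
directions and interpolating them is ill-defined without an
orientation-distribution model. Seeding is uniform over voxels above the QA
threshold with a random sub-voxel offset and a random direction slot;
propagation runs bidirectionally and the halves are concatenated. Everything
is driven by one recorded seed, and whole-volume runs are batched (all seeds
advance in lock-step through vectorized array operations, in chunks that
bound memory).

The track pool uses the negated cluster mask as terminative region, discards
tracks whose endpoints fall outside the clusters, and converts the survivors'
visited voxels into the pool ROI. The pool's QA threshold is 0.6 × Otsu of
the template QA over fiber voxels (falling back to 0.6 × the mean when all
fiber voxels share one value and the histogram is degenerate); the template
QA is used rather than any subject's.

## Post-hoc connectometry

One statistic serves both modes: the OLS t of the effect regressor — a
two-group indicator (threshold 2.0) or a continuous score (threshold 2.5) —
with an intercept and any nuisance columns (e.g. WNV) in the model. With no
nuisance the group mode reduces exactly to the pooled two-sample t (verified
in tests). Tracks are grown only along sign-matching suprathreshold features,
dropped below 40 mm, and pruned by topology-informed pruning: per round, the
per-voxel streamline density is computed and streamlines visiting voxels with
nonzero density below 20% of the mean nonzero density are removed (2 rounds
by default; the cutoff fraction is configurable). Group-comparison findings
are finally constrained to the omnibus pool: every point of a track must lie
inside the 1-voxel-dilated pool ROI.

Permutation FDR shuffles the effect regressor across subjects with nuisance
columns fixed (a Freedman–Lane-style simplification) and recomputes the t-map
and tracks with the same tracking seed. FDR(L) = mean permuted count of
tracks ≥ L divided by the observed count ≥ L, clipped to [0, 1]; candidate
lengths step by one voxel edge from the length threshold. Findings are the
observed tracks at the smallest L with FDR ≤ 0.05. FDR(L) is *not* guaranteed
monotone in L; only boundedness and identity-permutation consistency are
asserted. An empty observed track set reports FDR 1 and no findings.

Normalized QA divides each subject's features by that subject's maximum.
Variance explained is the squared Pearson correlation between the
(nuisance-residualized) score and each subject's mean normalized QA over the
ROI's features.

## Synthetic phantoms

The generator emulates the *inputs* of the pipeline, not raw diffusion
signal: no gradients, no reconstruction, no registration error. A phantom is
a set of straight cylindrical bundles (default: two orthogonal radius-2
bundles crossing at the center of a 40³ grid of 2 mm voxels, template SDF
0.6 and 0.5 against an isotropic floor of 0.1); bundle voxels carry the
bundle tangent, crossing voxels one direction per bundle. Cohorts default to
three groups of 28/16/8 subjects. Per-feature values are the template scaled
by (1 + fractional effect) for affected groups inside the planted segment,
plus Gaussian noise truncated at 0 (SDF is non-negative; no noise law is
canonical here and truncation preserves the invariant). The default noise SD
of 0.08 makes the default +20% effect on SDF 0.6 a standardized effect of
d ≈ 1.5.

Scores: the language composite follows
intercept + slope · (subject's normalized in-region mean SDF) + N(0, σ),
then splits symmetrically into PPVT4 and EVT2 so their mean reproduces it
exactly; WNV is an independent N(100, 15) nuisance. The score couples to the
*normalized* region mean because that is the predictor the
variance-explained analysis computes. When a target R² is requested, σ is
calibrated from the realized predictor variance as
σ² = var(slope · x)(1 − R²)/R², which makes the theoretical R² exact for the
realized cohort. On these phantoms the per-subject maximum is itself
noise-dominated, so coupling a score to the raw region mean would be almost
entirely attenuated by normalization — real SDF data, whose maxima sit in
stable high-anisotropy structures, is better behaved in this respect.

What phantom results do establish: correctness of the statistics against
independent oracles, geometric fidelity of the tracker, type-I-error control
and power of the full permutation pipeline under the stated noise model, and
bit-level reproducibility. What they do not establish: robustness to
registration error, heteroscedastic or spatially correlated noise, partial
volume effects, or curving anatomy — none of which the generator emulates.

## Problem sizes and presets

The desk preset (used by the tests and the acceptance script) runs the full
40³ phantom with 5,000 tracking seeds and 100–200 permutations per design,
keeping an end-to-end run in the seconds-to-minutes range on one CPU; the
production defaults (100,000 seeds, 4,000 permutations, FDR 0.05) are the
package defaults in `TrackingParams` and `DesignSpec`. Calibration and power
are measured over 50 null cohorts and 25 planted-effect replicates
respectively; R² recovery uses 20 cohorts of n = 200.

## Known limitations

- The tracker is Euler with nearest-voxel lookup; it is exact on straight
  axis-aligned bundles but will cut corners on strongly curving geometry.
- The outlier screen's non-idempotence (above) is inherent to leave-one-out
  z-scoring of small homogeneous groups.
- Permutation FDR inherits the discreteness of track counts: with few
  observed tracks the FDR estimate is coarse.
- Cluster correction is extent-only; no cluster-level p-values are computed.
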