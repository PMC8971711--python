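# lcanova — local-connectome ANOVA connectometry

`lcanova` implements a three-group extension of diffusion-MRI connectometry
for studies that compare white-matter structural connectivity across more
than two groups — the motivating design being extremely-preterm children
without (EPT) and with (EPT-HLD) a history of language delay versus term
comparisons (TC). It is aimed at researchers who have per-subject spin
distribution function (SDF) / quantitative anisotropy (QA) values in a common
template space and want a statistically principled way to restrict post-hoc
track-level comparisons to regions with omnibus evidence of a group
difference.

## The method

Each subject's **local connectome** is the vector of SDF values at every
(voxel, fiber direction) pair of a shared fiber geometry; stacking subjects
gives the connectometry database matrix **X** (subjects × features). The
pipeline then proceeds:

1. **Omnibus screen.** For every feature, a Kruskal–Wallis test across the
   k groups yields the rank-based omnibus statistic

   H = [12 / (N(N+1)) · Σᵢ nᵢ (R̄ᵢ − (N+1)/2)²] / [1 − Σ(t³−t)/(N³−N)],

   with mid-ranks and tie correction. A threshold of **0.6 × Otsu's
   threshold** on the H histogram selects features to carry forward.
2. **Cluster correction.** The voxel projection of passing features is
   filtered to 26-connected components of ≥ 20 voxels.
3. **Track pool.** The cluster mask's complement is used as a *terminative*
   region for deterministic whole-volume tractography (QA threshold =
   0.6 × Otsu of the template QA, angular threshold 60°); tracks ending
   outside the clusters are discarded and the surviving tracks' voxels form
   the pool ROI.
4. **Post-hoc connectometry.** Per feature, an OLS t statistic of a group
   indicator (t-threshold 2.0) or a behavioral score (t-threshold 2.5, with
   nuisance covariates such as the WNV general-ability score partialled out)
   defines the allowed feature set along which tracks are grown; tracks
   shorter than 40 mm are dropped and two rounds of topology-informed
   pruning remove stray streamlines.
5. **Permutation FDR.** The effect regressor is permuted across subjects and
   the track count recomputed; FDR(L) = mean permuted count of tracks ≥ L /
   observed count ≥ L, with findings reported at the smallest L with
   FDR ≤ 0.05.

The package also computes the **language composite** (mean of PPVT4 and EVT2
standardized scores) and the variance in it explained (R²) by mean normalized
QA over a finding's ROI.

Because clinical diffusion cohorts cannot be redistributed, `lcanova` ships a
first-class synthetic phantom module: crossing cylindrical fiber bundles on a
40³ grid of 2 mm voxels, three-group cohorts (default 28/16/8 subjects) with
planted regional SDF effects and score models with controllable theoretical
R². Every pipeline stage is tested end-to-end on these phantoms.

## Worked example

Generate a synthetic cohort with a +20% SDF effect planted in the EPT group
along one bundle segment, then run the full pipeline:

```bash
lcanova make-fixtures --out demo/cohort --seed 7 --n-per-group 28 16 8
# wrote cohort (52 subjects, 960 features) to demo/cohort

lcanova run --config examples/run.yaml \
    --db demo/cohort/connectome_db.zip --seed 7 --out demo/results
# pass fraction 0.330; pool tracks 1588; findings 1
```

`demo/results/report.json` records the thresholds and counts actually used:
the Otsu threshold on the H map was 10.28 (so features needed H > 6.17),
33.0% of SDF features passed, one 287-voxel cluster survived the 20-voxel
extent correction, and the EPT > TC contrast produced a finding of 4069
tracks at the 40 mm reporting length with permutation FDR 0.0 — the planted
segment, recovered. The finding's streamlines and ROI are written as
`finding_0_0p.trk` (+ JSON provenance sidecar) and `finding_0_0_roi.nii.gz`;
the negative contrast correctly yields nothing.

Correlational (within-group) connectometry against the language composite,
with WNV as nuisance:

```bash
lcanova within-group --db demo/cohort/connectome_db.zip \
    --score language_composite --nuisance wnv --seed 7 --out demo/within.json
```

## Layout

- `src/lcanova/connectome_db.py` — geometry, subject records, database, QC
- `src/lcanova/phantom.py` — synthetic phantoms and cohorts
- `src/lcanova/omnibus.py` — Kruskal–Wallis map, Otsu, clusters, track pool
- `src/lcanova/tracking.py` — deterministic streamline tractography
- `src/lcanova/connectometry.py` — t-maps, TIP, permutation FDR, R²
- `src/lcanova/pipeline.py`, `cli.py` — orchestration and the `lcanova` CLI
- `docs/methods.md` — modeling assumptions, parameter choices, limitations
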