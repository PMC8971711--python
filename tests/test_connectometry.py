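"""Regression t-maps, pruning, permutation FDR, normalized QA, R^2."""

import numpy as np
import pytest
from scipy import stats

from _helpers import dice
from lcanova.connectome_db import SubjectRecord
from lcanova.connectometry import (
    DesignSpec,
    connectometry_tracks,
    feature_t_map,
    language_composite,
    normalize_qa,
    permutation_fdr,
    residualize,
    topology_informed_pruning,
    variance_explained,
)
from lcanova.omnibus import StatisticMap
from lcanova.phantom import effect_voxel_mask
from lcanova.tracking import TrackingParams, Tractogram, tracks_to_roi


def _params(**kw):
    defaults = dict(qa_threshold=0.3, min_length=10.0, max_length=400.0, n_seeds=3000, seed=0)
    defaults.update(kw)
    return TrackingParams(**defaults)


class TestResidualize:
    def test_no_covariates_demeans(self):
        y = np.array([1.0, 2.0, 6.0])
        np.testing.assert_allclose(residualize(y, None), y - 3.0)

    def test_perfect_fit_zero_residuals(self):
        x = np.arange(10.0)
        y = 3.0 * x + 2.0
        np.testing.assert_allclose(residualize(y, x), 0.0, atol=1e-10)

    def test_matches_hat_matrix(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=20)
        y = rng.normal(size=20)
        X = np.column_stack([np.ones(20), x])
        H = X @ np.linalg.inv(X.T @ X) @ X.T
        np.testing.assert_allclose(residualize(y, x), y - H @ y, atol=1e-10)

    def test_orthogonal_to_covariates(self):
        rng = np.random.default_rng(1)
        C = rng.normal(size=(30, 2))
        r = residualize(rng.normal(size=30), C)
        scale = np.abs(C).max()
        assert np.all(np.abs(C.T @ r) / scale < 1e-8)

    def test_collinear_covariates_error(self):
        x = np.arange(10.0)
        with pytest.raises(ValueError, match="rank deficient"):
            residualize(x, np.column_stack([x, 2.0 * x]))


class TestFeatureTMap:
    def test_two_group_equals_pooled_t(self, null_db):
        design = DesignSpec(mode="group_compare", contrast=("EPT", "TC"), n_permutations=100)
        tmap = feature_t_map(null_db, design)
        labels = null_db.group_labels()
        a = null_db.matrix[labels == "EPT"]
        b = null_db.matrix[labels == "TC"]
        ref = stats.ttest_ind(a, b, axis=0).statistic
        np.testing.assert_allclose(tmap.values, ref, atol=1e-10)

    def test_separation_sign(self, geometry, phantom_spec):
        from lcanova.phantom import EffectSpec, simulate_cohort

        eff = EffectSpec(frac_change=0.5)
        db, truth = simulate_cohort(
            geometry, phantom_spec, eff, n_per_group=(4, 4, 2), noise_sd=0.001, rng=0
        )
        design = DesignSpec(contrast=("EPT", "TC"), n_permutations=100)
        t = feature_t_map(db, design).values
        assert np.all(t[truth] > 50)  # near-separation: huge positive t

    def test_label_swap_flips_sign(self, null_db):
        d1 = DesignSpec(contrast=("EPT", "TC"), n_permutations=100)
        d2 = DesignSpec(contrast=("TC", "EPT"), n_permutations=100)
        np.testing.assert_allclose(
            feature_t_map(null_db, d1).values, -feature_t_map(null_db, d2).values, atol=1e-10
        )

    def test_affine_feature_rescale_invariance(self, null_db):
        import copy

        design = DesignSpec(contrast=("EPT", "TC"), n_permutations=100)
        t1 = feature_t_map(null_db, design).values
        scaled = copy.deepcopy(null_db)
        scaled.matrix = scaled.matrix * 3.7
        t2 = feature_t_map(scaled, design).values
        np.testing.assert_allclose(t1, t2, atol=1e-8)

    def test_null_tail_fraction_matches_t_distribution(self, null_db):
        design = DesignSpec(contrast=("EPT", "TC"), n_permutations=100)
        t = feature_t_map(null_db, design).values
        n = (null_db.group_labels() == "EPT").sum() + (null_db.group_labels() == "TC").sum()
        df = n - 2
        expected = 2 * stats.t.sf(2.0, df)
        observed = (np.abs(t) > 2.0).mean()
        # binomial tolerance over ~1000 (correlated) features
        assert observed == pytest.approx(expected, abs=0.035)


class TestConnectometryTracks:
    def test_recovers_planted_segment(self, planted_db, geometry, phantom_spec, effect_spec):
        db, truth = planted_db
        design = DesignSpec(contrast=("EPT", "TC"), n_permutations=100)
        tmap = feature_t_map(db, design)
        tracks = connectometry_tracks(tmap, "+", design, geometry, _params())
        assert len(tracks) > 0
        assert np.all(tracks.lengths() >= design.length_threshold)
        roi = tracks_to_roi(tracks, geometry)
        truth_vox = effect_voxel_mask(geometry, phantom_spec, effect_spec)
        assert dice(roi, truth_vox) >= 0.5

    def test_opposite_sign_empty_for_one_sided_planting(
        self, planted_db, geometry
    ):
        db, _ = planted_db
        design = DesignSpec(contrast=("EPT", "TC"), n_permutations=100)
        tmap = feature_t_map(db, design)
        tracks = connectometry_tracks(tmap, "-", design, geometry, _params())
        assert len(tracks) == 0

    def test_infinite_threshold_empty(self, planted_db, geometry):
        db, _ = planted_db
        design = DesignSpec(contrast=("EPT", "TC"), t_threshold=1e9, n_permutations=100)
        tmap = feature_t_map(db, design)
        assert len(connectometry_tracks(tmap, "+", design, geometry, _params())) == 0


class TestTopologyInformedPruning:
    def _bundle_tractogram(self, geometry):
        rng = np.random.default_rng(2)
        lines = []
        for _ in range(50):
            y = 40.0 + rng.uniform(-2, 2)
            z = 40.0 + rng.uniform(-2, 2)
            xs = np.arange(10.0, 70.0, 1.0)
            lines.append(np.column_stack([xs, np.full_like(xs, y), np.full_like(xs, z)]))
        return lines

    def test_stray_streamline_removed_bundle_intact(self, geometry):
        lines = self._bundle_tractogram(geometry)
        stray = np.column_stack(
            [np.arange(10.0, 70.0, 1.0), np.arange(10.0, 70.0, 1.0), np.full(60, 10.0)]
        )
        tg = Tractogram(lines + [stray], 1.0)
        pruned = topology_informed_pruning(tg, geometry, rounds=2)
        assert len(pruned) == len(lines)
        assert not any(np.array_equal(s, stray) for s in pruned.streamlines)

    def test_zero_rounds_is_identity(self, geometry):
        tg = Tractogram(self._bundle_tractogram(geometry), 1.0)
        pruned = topology_informed_pruning(tg, geometry, rounds=0)
        assert len(pruned) == len(tg)

    def test_monotone_shrinkage_across_rounds(self, geometry):
        lines = self._bundle_tractogram(geometry)
        rng = np.random.default_rng(3)
        for _ in range(5):  # a few scattered strays
            y0, z0 = rng.uniform(10, 70, 2)
            xs = np.arange(20.0, 60.0, 1.0)
            lines.append(np.column_stack([xs, np.full_like(xs, y0), np.full_like(xs, z0)]))
        tg = Tractogram(lines, 1.0)
        kept = [len(topology_informed_pruning(tg, geometry, rounds=r)) for r in range(4)]
        assert all(a >= b for a, b in zip(kept, kept[1:]))


class TestPermutationFDR:
    def test_identity_permutation_reproduces_observed_count(
        self, planted_db, geometry
    ):
        # with the unpermuted regressor the recomputed track count equals the
        # observed count exactly (same t-map, same seeded tracking)
        db, _ = planted_db
        design = DesignSpec(contrast=("EPT", "TC"), n_permutations=100, tip_rounds=0)
        tmap = feature_t_map(db, design)
        params = _params(seed=4)
        observed = connectometry_tracks(tmap, "+", design, geometry, params)
        again = connectometry_tracks(tmap, "+", design, geometry, params)
        assert len(again) == len(observed)
        np.testing.assert_array_equal(observed.lengths(), again.lengths())

    def test_planted_effect_reaches_low_fdr(self, planted_db, geometry):
        db, _ = planted_db
        design = DesignSpec(contrast=("EPT", "TC"), n_permutations=100, seed=1)
        tmap = feature_t_map(db, design)
        params = _params(seed=1)
        observed = connectometry_tracks(tmap, "+", design, geometry, params)
        fdr_table, findings = permutation_fdr(
            db, design, geometry, params, observed, sign="+"
        )
        assert all(0.0 <= f <= 1.0 for f in fdr_table.values())
        assert len(findings) == 1
        assert findings[0].fdr <= design.fdr_level
        assert np.all(findings[0].tracks.lengths() >= findings[0].length_mm)

    def test_empty_observed_reports_fdr_one(self, null_db, geometry):
        design = DesignSpec(contrast=("EPT", "TC"), n_permutations=100)
        empty = Tractogram([], 1.0)
        fdr_table, findings = permutation_fdr(
            null_db, design, geometry, _params(), empty, sign="+"
        )
        assert findings == []
        assert fdr_table[design.length_threshold] == 1.0


class TestNormalizeQA:
    def test_scale_invariance(self):
        rng = np.random.default_rng(5)
        x = rng.random((4, 20)) + 0.1
        np.testing.assert_allclose(normalize_qa(x), normalize_qa(7.3 * x), atol=1e-12)

    def test_division_by_subject_max(self):
        x = np.array([[1.0, 2.0, 4.0]])
        np.testing.assert_allclose(normalize_qa(x), [[0.25, 0.5, 1.0]])

    def test_all_zero_subject_errors(self):
        with pytest.raises(ValueError, match="normalize"):
            normalize_qa(np.zeros((2, 3)))

    def test_group_ordering_preserved_in_region(self, planted_db):
        db, truth = planted_db
        labels = db.group_labels()
        normed = normalize_qa(db.matrix)
        ept = normed[labels == "EPT"][:, truth].mean()
        tc = normed[labels == "TC"][:, truth].mean()
        assert ept > tc  # planted positive effect survives normalization


class TestVarianceExplained:
    def test_perfect_linear_score(self, geometry, phantom_spec):
        from lcanova.phantom import EffectSpec, simulate_cohort

        eff = EffectSpec(groups=("TC", "EPT", "EPT_HLD"))
        db, truth = simulate_cohort(
            geometry, phantom_spec, eff, n_per_group=(5, 4, 3), rng=6
        )
        roi = np.zeros(geometry.dims, bool)
        ijk, _, _ = geometry.feature_table()
        sel = ijk[truth]
        roi[sel[:, 0], sel[:, 1], sel[:, 2]] = True
        normed = normalize_qa(db.matrix)
        fmask = roi[ijk[:, 0], ijk[:, 1], ijk[:, 2]]
        x = normed[:, fmask].mean(axis=1)
        for rec, xi in zip(db.active_subjects, x):
            rec.scores["lin"] = float(10.0 + 5.0 * xi)
        assert variance_explained(db, roi, "lin") == pytest.approx(1.0, abs=1e-9)

    def test_null_r2_expectation(self, geometry, phantom_spec):
        # under independence E[R^2] = 1/(n-1)
        from lcanova.phantom import null_cohort

        rng = np.random.default_rng(7)
        roi = np.ones(geometry.dims, bool)
        n = 26
        r2s = []
        for rep in range(40):
            db = null_cohort(geometry, phantom_spec, n_per_group=(10, 10, 6), rng=100 + rep)
            for rec in db.active_subjects:
                rec.scores["noise"] = float(rng.normal())
            r2s.append(variance_explained(db, roi, "noise"))
        assert np.mean(r2s) == pytest.approx(1.0 / (n - 1), abs=0.025)

    def test_r2_recovery_at_target(self, geometry, phantom_spec):
        from lcanova.phantom import EffectSpec, simulate_cohort
        from lcanova.connectometry import language_composite

        eff = EffectSpec(groups=("TC", "EPT", "EPT_HLD"), target_r2=0.55)
        db, truth = simulate_cohort(
            geometry, phantom_spec, eff, n_per_group=(100, 60, 40), rng=8
        )
        comp = language_composite(db.active_subjects)
        for rec, c in zip(db.active_subjects, comp):
            rec.scores["language_composite"] = float(c)
        roi = np.zeros(geometry.dims, bool)
        ijk, _, _ = geometry.feature_table()
        sel = ijk[truth]
        roi[sel[:, 0], sel[:, 1], sel[:, 2]] = True
        r2 = variance_explained(db, roi, "language_composite")
        assert r2 == pytest.approx(0.55, abs=0.10)


class TestLanguageComposite:
    def test_identity_and_arithmetic(self):
        recs = [
            SubjectRecord(id="a", group="TC", scores={"ppvt4": 100.0, "evt2": 100.0}),
            SubjectRecord(id="b", group="TC", scores={"ppvt4": 110.0, "evt2": 90.0}),
        ]
        np.testing.assert_allclose(language_composite(recs), [100.0, 100.0])

    def test_composite_of_group_means_is_mean_of_composites(self):
        # linearity: group mean PPVT4 111 and EVT2 107 force composite 109
        rng = np.random.default_rng(9)
        ppvt = 111.0 + rng.normal(0, 13, 16)
        evt = 107.0 + rng.normal(0, 11, 16)
        ppvt += 111.0 - ppvt.mean()
        evt += 107.0 - evt.mean()
        recs = [
            SubjectRecord(id=f"e{i}", group="EPT", scores={"ppvt4": float(p), "evt2": float(e)})
            for i, (p, e) in enumerate(zip(ppvt, evt))
        ]
        assert language_composite(recs).mean() == pytest.approx(109.0, abs=1e-9)

    def test_missing_score_names_subject(self):
        recs = [SubjectRecord(id="x1", group="TC", scores={"ppvt4": 100.0})]
        with pytest.raises(ValueError, match="x1"):
            language_composite(recs)
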