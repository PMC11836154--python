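"""Atlas fitting, patient sampling, aBMD projection and cohort assembly."""

import numpy as np
import pytest
from scipy import stats

from silicofem import (
    AnthropometryParams,
    CohortTarget,
    FeatureROI,
    ProjectionROI,
    SoftTissueParams,
    build_cohort,
    compute_aBMD,
    fit_atlas,
    sample_anthropometry,
    sample_features,
    sample_patient_features,
    soft_tissue_thickness,
)
from silicofem.atlas import CohortInfeasibleError, _sample_scores
from silicofem.fixtures import make_box_tet10_mesh


class TestFitAtlas:
    def test_training_rows_reconstructed_exactly(self, default_atlas, default_training):
        X, _ = default_training
        rec = default_atlas.reconstruct(default_atlas.transform(X))
        assert np.allclose(rec, X, atol=1e-8)

    def test_component_count_is_n_train_minus_one(self, default_atlas):
        # 94 training femurs give 93 stochastic variables
        assert default_atlas.K == 93
        assert default_atlas.score_samples.shape == (94, 93)

    def test_modes_orthonormal_and_scores_centred(self, default_atlas):
        G = default_atlas.modes.T @ default_atlas.modes
        assert np.allclose(G, np.eye(default_atlas.K), atol=1e-8)
        assert np.allclose(default_atlas.score_samples.mean(axis=0), 0, atol=1e-8)

    def test_explained_variance_decreasing(self, default_atlas):
        assert np.all(np.diff(default_atlas.explained_variance) <= 1e-12)

    def test_collinear_rows_give_single_component_along_line(self):
        # rows c + t*d: the 2x2 eigenproblem by hand has one non-trivial
        # eigenvector equal to the line direction
        d = np.array([1.0, 2.0, 2.0]) / 3.0
        c = np.array([5.0, -1.0, 2.0])
        X = c + np.outer([-1.0, 0.0, 1.0], d)
        with pytest.warns(RuntimeWarning, match="rank-deficient"):
            atlas = fit_atlas(X)
        assert atlas.K == 1
        load = atlas.modes[:, 0]
        assert np.allclose(np.abs(load @ d), 1.0, atol=1e-10)

    @pytest.mark.parametrize(
        "bad",
        [
            np.full((3, 4), np.nan),
            np.array([[1.0, np.inf, 0, 0], [0, 1, 0, 0], [0, 0, 1, 0]]),
        ],
    )
    def test_nonfinite_rejected(self, bad):
        with pytest.raises(ValueError, match="non-finite"):
            fit_atlas(bad)

    def test_wide_matrix_required(self):
        with pytest.raises(ValueError, match="P >= n_train"):
            fit_atlas(np.random.default_rng(0).normal(size=(10, 4)))


class TestSampling:
    def test_zero_scores_decode_to_mean(self, default_atlas):
        out = default_atlas.reconstruct(np.zeros(default_atlas.K))
        assert np.allclose(out, default_atlas.mean_features)

    def test_median_quantile_returns_training_median(self, default_atlas):
        class HalfRNG:
            def uniform(self, size):
                return np.full(size, 0.5)

        scores = _sample_scores(default_atlas, 1, HalfRNG())
        expect = np.median(default_atlas.score_samples, axis=0)
        assert np.allclose(scores[0], expect)

    def test_sampled_scores_match_training_distribution(self, default_atlas, rng):
        feats = sample_features(default_atlas, rng, size=10_000)
        scores = default_atlas.transform(feats)
        for k in range(5):  # leading components carry nearly all the variance
            _, p = stats.ks_2samp(scores[:, k], default_atlas.score_samples[:, k])
            assert p > 0.01

    def test_single_patient_vector_shape(self, default_atlas, rng):
        f = sample_patient_features(default_atlas, rng)
        assert f.shape == (default_atlas.n_features,)


class TestComputeABMD:
    @staticmethod
    def _slab_features(density, cells=(4, 2, 2), cell=10.0):
        nodes, elements, _ = make_box_tet10_mesh(cells, cell)
        feats = np.concatenate([nodes.ravel(), np.full(len(elements), density)])
        roi = ProjectionROI(n_nodes=len(nodes), elements=elements)
        return feats, roi

    def test_uniform_slab_equals_density_times_thickness(self):
        # slab 40x20 mm coronal, 20 mm thick along y -> aBMD = rho * 2 cm
        rho = 0.8
        feats, roi = self._slab_features(rho)
        assert compute_aBMD(feats, roi) == pytest.approx(rho * 2.0, rel=1e-9)

    def test_linear_in_density(self):
        feats, roi = self._slab_features(0.5)
        nodes_part = feats[: 3 * roi.n_nodes]
        doubled = np.concatenate([nodes_part, 2 * feats[3 * roi.n_nodes :]])
        assert compute_aBMD(doubled, roi) == pytest.approx(2 * compute_aBMD(feats, roi), rel=1e-12)

    def test_zero_density_gives_zero(self):
        feats, roi = self._slab_features(0.0)
        assert compute_aBMD(feats, roi) == 0.0

    def test_empty_window_rejected(self):
        feats, roi = self._slab_features(1.0)
        bad = ProjectionROI(n_nodes=roi.n_nodes, elements=roi.elements, window=(1e3, 2e3, 1e3, 2e3))
        with pytest.raises(ValueError, match="empty ROI"):
            compute_aBMD(feats, bad)

    def test_feature_roi_reads_feature(self):
        assert compute_aBMD(np.array([1.0, 0.71, 3.0]), FeatureROI(1)) == 0.71


class TestAnthropometry:
    def test_bmi_definition(self, rng):
        h, w, bmi = sample_anthropometry(0.6, rng)
        assert bmi == pytest.approx(w / h**2, abs=1e-12)
        p = AnthropometryParams(height_sd=1e-12, weight_sd=1e-12, height_mean=1.60, weight_mean=64.0)
        _, _, bmi = sample_anthropometry(0.6, rng, p)
        assert bmi == pytest.approx(25.0, rel=1e-9)

    def test_correlation_recovered(self, rng):
        neck = rng.normal(0.56, 0.08, 20_000)
        neck = np.clip(neck, 1e-3, None)
        h, w, _ = sample_anthropometry(neck, rng)
        assert np.corrcoef(w, neck)[0, 1] == pytest.approx(0.4, abs=0.02)
        assert np.corrcoef(h, neck)[0, 1] == pytest.approx(0.4, abs=0.02)
        assert np.corrcoef(h, w)[0, 1] == pytest.approx(0.5, abs=0.02)

    def test_zero_correlation_gives_independence(self, rng):
        neck = np.clip(rng.normal(0.56, 0.08, 20_000), 1e-3, None)
        p = AnthropometryParams(corr_abmd=0.0)
        h, _, _ = sample_anthropometry(neck, rng, p)
        assert abs(np.corrcoef(h, neck)[0, 1]) < 0.02

    def test_nonpositive_abmd_rejected(self, rng):
        with pytest.raises(ValueError):
            sample_anthropometry(-0.1, rng)


class TestSoftTissue:
    def test_default_line(self):
        assert soft_tissue_thickness(25.0) == pytest.approx(20.0)

    def test_zero_slope_is_constant(self):
        p = SoftTissueParams(intercept=15.0, slope=0.0)
        assert soft_tissue_thickness(18.0, p) == soft_tissue_thickness(40.0, p) == 15.0

    def test_floor_clip(self):
        # -10 + 1.2*5 = -4, clipped to the 2 mm floor
        assert soft_tissue_thickness(5.0) == 2.0

    def test_monotone_in_bmi(self):
        bmi = np.linspace(10, 45, 100)
        stt = soft_tissue_thickness(bmi)
        assert np.all(np.diff(stt) >= 0)


class TestBuildCohort:
    def test_identity_target_accepts_freely(self, default_atlas, rng):
        pre = sample_features(default_atlas, rng, size=2000)
        abmd = pre[:, default_atlas.feature_meta["total_hip_abmd_index"]]
        target = CohortTarget(300, float(abmd.mean()), float(abmd.std(ddof=1)))
        cohort = build_cohort(default_atlas, target, rng)
        vals = np.array([p.total_hip_aBMD for p in cohort])
        assert len(cohort) == 300
        assert abs(vals.mean() - target.aBMD_mean) < 3 * target.aBMD_sd / np.sqrt(300)

    def test_target_distribution_matched(self, default_atlas, rng):
        target = CohortTarget(600, 0.722, 0.096)
        cohort = build_cohort(default_atlas, target, rng)
        vals = np.array([p.total_hip_aBMD for p in cohort])
        ref = rng.normal(target.aBMD_mean, target.aBMD_sd, 600)
        _, p = stats.ttest_ind(vals, ref, equal_var=True)
        assert abs(vals.mean() - 0.722) < 2 * 0.096 / np.sqrt(600)
        assert p > 0.05

    def test_infeasible_target_aborts(self, default_atlas, rng):
        with pytest.raises(CohortInfeasibleError):
            build_cohort(default_atlas, CohortTarget(100, 5.0, 0.05), rng)

    def test_patients_fully_specified(self, default_atlas, rng, surrogate):
        cohort = build_cohort(default_atlas, CohortTarget(20, 0.722, 0.096), rng, surrogate=surrogate)
        for p in cohort:
            assert p.state == "active" and p.fracture_year is None
            assert p.total_hip_aBMD > 0 and p.neck_aBMD > 0
            assert p.soft_tissue_thickness >= 2.0
            assert p.strength is not None
            assert p.BMI == pytest.approx(p.weight / p.height**2, abs=1e-9)
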