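"""PCA shape models: dual-form correctness, synthesis, projection, regions."""

import numpy as np
import pytest

from rssm.curvature import RegionLabeling, gaussian_curvature, partition_regions
from rssm.mesh import TriangleMesh
from rssm.registration import generalized_procrustes
from rssm.shape_model import (cumulative_variance, fit_rssm, fit_ssm, project,
                              sd_model, sd_model_regional, synthesize,
                              synthesize_regional)
from rssm.synthetic import (PopulationConfig, build_template,
                            sample_localized_population, sample_population)


def _random_cohort(rng, n, V):
    """Small random corresponded cohort with a ring connectivity."""
    faces = np.array([[i, (i + 1) % V, (i + 2) % V] for i in range(V)])
    base = rng.normal(size=(V, 3)) * 5
    return [TriangleMesh(base + rng.normal(0, 0.5, size=(V, 3)), faces)
            for _ in range(n)]


class TestFitSsm:
    def test_identical_meshes_all_variance_zero(self, template):
        model = fit_ssm([template.copy() for _ in range(5)])
        assert np.allclose(model.variances, 0.0)
        assert np.allclose(model.mean, template.vertices.ravel())
        assert model.n_modes == 4   # n - 1, orthonormal completion
        G = model.components.T @ model.components
        assert np.allclose(G, np.eye(4), atol=1e-9)

    def test_agrees_with_dense_covariance_eigendecomposition(self):
        # independent oracle: eigh of the full 3V x 3V covariance matrix
        rng = np.random.default_rng(21)
        for trial in range(5):
            n = int(rng.integers(4, 20))
            V = int(rng.integers(10, 200))
            meshes = _random_cohort(rng, n, V)
            model = fit_ssm(meshes)
            X = np.stack([m.vertices.ravel() for m in meshes])
            S = np.cov(X.T)
            evals = np.linalg.eigvalsh(S)[::-1][:n - 1]
            pos = evals > evals[0] * 1e-10
            assert np.allclose(model.variances[pos], evals[pos], rtol=1e-8)

    def test_single_known_mode_recovered(self, template):
        # generator oracle: one unit displacement field, normal weights
        rng = np.random.default_rng(3)
        d = rng.normal(size=template.vertices.shape)
        d /= np.linalg.norm(d)
        sigma = 0.8
        w = rng.normal(0, sigma, size=500)
        meshes = [template.with_vertices(template.vertices + wi * d)
                  for wi in w]
        model = fit_ssm(meshes)
        cosang = abs(model.components[:, 0] @ d.ravel())
        assert cosang > 0.999
        assert model.variances[0] == pytest.approx(sigma ** 2, rel=0.2)
        assert model.variances[1] < 1e-12 * model.variances[0] + 1e-12

    def test_mode_count_limited_to_n_minus_one(self, template):
        meshes = [template.copy() for _ in range(4)]
        with pytest.raises(ValueError, match="n - 1"):
            fit_ssm(meshes, n_modes=4)
        model = fit_ssm(meshes, n_modes=3)
        assert model.n_modes == 3

    def test_variance_conservation(self):
        rng = np.random.default_rng(8)
        meshes = _random_cohort(rng, 12, 50)
        model = fit_ssm(meshes)
        X = np.stack([m.vertices.ravel() for m in meshes])
        total = ((X - X.mean(axis=0)) ** 2).sum() / (len(X) - 1)
        assert model.variances.sum() == pytest.approx(total, rel=1e-9)


@pytest.fixture(scope="module")
def fitted():
    rng = np.random.default_rng(5)
    meshes = _random_cohort(rng, 10, 60)
    return fit_ssm(meshes), meshes


class TestSynthesisProjection:
    def test_zero_weights_give_mean(self, fitted):
        model, _ = fitted
        out = synthesize(model, np.zeros(model.n_modes))
        assert np.array_equal(out.vertices.ravel(), model.mean)

    def test_full_mode_reconstruction_of_training_meshes(self, fitted):
        model, meshes = fitted
        for m in meshes:
            w = project(model, m)
            rec = synthesize(model, w)
            rms = np.sqrt(((rec.vertices - m.vertices) ** 2).sum(axis=1).mean())
            assert rms < 1e-8

    def test_project_synthesize_round_trip(self, fitted):
        model, _ = fitted
        rng = np.random.default_rng(0)
        w0 = rng.normal(size=model.n_modes)
        w = project(model, synthesize(model, w0))
        assert np.allclose(w, w0, atol=1e-10)

    def test_mean_projects_to_zero(self, fitted):
        model, _ = fitted
        assert np.allclose(project(model, model.mean_mesh()), 0, atol=1e-10)

    def test_sd_model_symmetry_about_mean(self, fitted):
        model, _ = fitted
        hi = sd_model(model, 0, +2.0)
        lo = sd_model(model, 0, -2.0)
        assert np.allclose((hi.vertices + lo.vertices) / 2.0,
                           model.mean.reshape(-1, 3), atol=1e-12)

    def test_sd_model_equals_explicit_weight(self, fitted):
        model, _ = fitted
        w = np.zeros(model.n_modes)
        w[1] = 2.0 * np.sqrt(model.variances[1])
        assert np.array_equal(sd_model(model, 1, 2.0).vertices,
                              synthesize(model, w).vertices)

    def test_zero_variance_mode_warns_and_returns_mean(self, template):
        model = fit_ssm([template.copy() for _ in range(3)])
        with pytest.warns(RuntimeWarning):
            out = sd_model(model, 0, 2.0)
        assert np.array_equal(out.vertices.ravel(), model.mean)

    def test_nonfinite_weights_rejected(self, fitted):
        model, _ = fitted
        with pytest.raises(ValueError):
            synthesize(model, [np.nan])


class TestModeRecovery:
    def test_generator_modes_recovered_and_size_dominant(self):
        # the generator's latent weights are the oracle
        cfg = PopulationConfig(n_subjects=200, seed=20230001)
        s = sample_population(cfg)
        aligned, _ = generalized_procrustes(s.meshes)
        model = fit_ssm(aligned)
        W = np.column_stack([project(model, m)[:4] for m in aligned]).T
        L = s.weights_array()
        C = np.abs(np.corrcoef(np.hstack([L, W]).T)[:4, 4:])
        assert (C.max(axis=1) > 0.9).all()
        # size is PC1: largest single-mode variance fraction
        assert C[0, 0] > 0.9
        frac = cumulative_variance(model)["fractions"]
        assert frac[0] == frac.max()


@pytest.fixture(scope="module")
def cohort_and_labeling():
    cfg = PopulationConfig(n_subjects=12, vertex_noise_sd=0.02,
                           misalign_rotation_sd=0.0,
                           misalign_translation_sd=0.0, seed=9)
    s = sample_population(cfg)
    aligned, _ = generalized_procrustes(s.meshes)
    tpl = aligned[0]
    lab = partition_regions(gaussian_curvature(tpl), tpl)
    return aligned, lab


class TestRegionalModel:
    def test_single_region_reduces_to_global_model(self, cohort_and_labeling):
        aligned, _ = cohort_and_labeling
        V = aligned[0].vertex_count
        lab1 = RegionLabeling(np.zeros(V, int), 1, V, single_sign=True)
        r = fit_rssm(aligned, lab1)
        g = fit_ssm(aligned)
        sub = r.region_models[0]
        assert np.allclose(sub.mean, g.mean)
        assert np.allclose(sub.variances, g.variances, rtol=1e-9, atol=1e-12)
        assert np.allclose(np.abs(sub.components.T @ g.components),
                           np.eye(g.n_modes), atol=1e-6)

    def test_regional_variance_bookkeeping(self, cohort_and_labeling):
        # oracle: per-region coordinate variance computed directly
        aligned, lab = cohort_and_labeling
        r = fit_rssm(aligned, lab)
        X = np.stack([m.vertices for m in aligned])
        for reg in range(lab.n_regions):
            idx = lab.region_indices(reg)
            Xr = X[:, idx, :].reshape(len(aligned), -1)
            total = ((Xr - Xr.mean(axis=0)) ** 2).sum() / (len(aligned) - 1)
            assert r.region_models[reg].variances.sum() == \
                pytest.approx(total, rel=1e-9)

    def test_variation_confined_to_one_region(self, template):
        # all displacement on region-1 vertices: region-0 variances vanish
        lab = partition_regions(gaussian_curvature(template), template)
        mask = lab.labels == 1
        meshes, w, fld = sample_localized_population(template, mask, 10, 0.5,
                                                     seed=4)
        r = fit_rssm(meshes, lab)
        total = sum(m.variances.sum() for m in r.region_models)
        assert r.region_models[0].variances.sum() < 1e-6 * total

    def test_regional_sd_synthesis_keeps_other_regions_at_mean(
            self, cohort_and_labeling):
        aligned, lab = cohort_and_labeling
        r = fit_rssm(aligned, lab)
        out = sd_model_regional(r, 1, 0, 2.0)
        mean = r.full_mean()
        idx0 = lab.region_indices(0)
        assert np.array_equal(out.vertices[idx0], mean[idx0])
        idx1 = lab.region_indices(1)
        assert not np.allclose(out.vertices[idx1], mean[idx1])


class TestCumulativeVariance:
    def test_final_cumulative_is_one(self):
        rng = np.random.default_rng(2)
        model = fit_ssm(_random_cohort(rng, 8, 40))
        cv = cumulative_variance(model)
        assert cv["cumulative"][-1] == pytest.approx(1.0, abs=1e-12)
        assert (np.diff(cv["cumulative"]) >= -1e-15).all()

    def test_single_mode_cohort_first_fraction_near_one(self, template):
        rng = np.random.default_rng(13)
        d = rng.normal(size=template.vertices.shape)
        d /= np.linalg.norm(d)
        meshes = [template.with_vertices(
            template.vertices + rng.normal(0, 1.0) * d
            + rng.normal(0, 1e-4, template.vertices.shape)) for _ in range(20)]
        cv = cumulative_variance(fit_ssm(meshes))
        assert cv["fractions"][0] > 0.999

    def test_known_variance_budget(self, template):
        # 2 orthogonal generator modes at 85/15 variance split; the first-2
        # cumulative must approach 0.85 + 0.15 = 1 and mode 1 fraction 0.85
        rng = np.random.default_rng(31)
        d1 = rng.normal(size=template.vertices.shape)
        d1 /= np.linalg.norm(d1)
        d2 = rng.normal(size=template.vertices.shape)
        d2 -= (d2.ravel() @ d1.ravel()) * d1
        d2 /= np.linalg.norm(d2)
        v1, v2 = 0.85, 0.15
        meshes = [template.with_vertices(
            template.vertices + rng.normal(0, np.sqrt(v1)) * d1
            + rng.normal(0, np.sqrt(v2)) * d2) for _ in range(500)]
        cv = cumulative_variance(fit_ssm(meshes))
        assert cv["fractions"][0] == pytest.approx(0.85, abs=0.04)
        assert cv["cumulative"][1] == pytest.approx(1.0, abs=1e-9)
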