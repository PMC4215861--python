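"""PCA shape atlas: eigenstructure oracles, projections, mode interpretation."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from lvatlas.atlas import (build_pca, concatenate_frames, interpret_modes,
                           mode_extreme_shape, mode_scores_table, project,
                           reconstruct, split_frames)


def data_with_spectrum(eigenvalues, n, rng):
    """Construct an (n, d) sample whose covariance has exactly the requested
    eigenvalues (orthogonal columns scaled to the target variances)."""
    d = len(eigenvalues)
    z = rng.standard_normal((n, d))
    z -= z.mean(axis=0)
    q, _ = np.linalg.qr(z)
    return q * np.sqrt((n - 1) * np.asarray(eigenvalues))


class TestBuildPca:
    def test_rank_one_data_has_single_mode(self):
        rng = np.random.default_rng(0)
        direction = rng.standard_normal(6)
        x = np.outer(rng.standard_normal(20), direction)
        atlas = build_pca(x)
        assert atlas.variance_fractions[0] == pytest.approx(1.0, abs=1e-10)
        assert atlas.n_retained == 1

    def test_constructed_spectrum_cumulative_fractions_and_retention(self):
        """Eigenvalues (5, 3, 1, 1) give cumulative fractions (.5, .8, .9, 1)
        and the 90% rule retains exactly 3 modes."""
        rng = np.random.default_rng(1)
        x = data_with_spectrum([5.0, 3.0, 1.0, 1.0], n=12, rng=rng)
        atlas = build_pca(x, variance_threshold=0.90)
        np.testing.assert_allclose(atlas.eigenvalues, [5, 3, 1, 1], atol=1e-9)
        np.testing.assert_allclose(atlas.cumulative_variance,
                                   [0.5, 0.8, 0.9, 1.0], atol=1e-10)
        assert atlas.n_retained == 3

    def test_svd_route_matches_dense_covariance_eigendecomposition(self):
        rng = np.random.default_rng(2)
        x = rng.standard_normal((30, 10)) * np.linspace(3, 0.5, 10)
        atlas = build_pca(x)
        cov = np.cov(x, rowvar=False, ddof=1)
        w, v = np.linalg.eigh(cov)
        w, v = w[::-1], v[:, ::-1]
        np.testing.assert_allclose(atlas.eigenvalues, w[:len(atlas.eigenvalues)],
                                   atol=1e-8)
        for k in range(atlas.modes.shape[1]):
            dot = abs(float(atlas.modes[:, k] @ v[:, k]))
            assert dot == pytest.approx(1.0, abs=1e-8)

    def test_dual_route_matches_direct_route(self):
        """n < d triggers the Gram-matrix route; it must agree with the
        direct SVD of the transposed-size problem to 1e-8."""
        rng = np.random.default_rng(3)
        x = rng.standard_normal((10, 30)) + rng.standard_normal((10, 1))
        atlas_dual = build_pca(x)                       # d=30 > n=10
        cov = np.cov(x, rowvar=False, ddof=1)
        w = np.linalg.eigvalsh(cov)[::-1]
        np.testing.assert_allclose(atlas_dual.eigenvalues,
                                   w[:len(atlas_dual.eigenvalues)], atol=1e-8)
        assert np.allclose(atlas_dual.modes.T @ atlas_dual.modes,
                           np.eye(atlas_dual.modes.shape[1]), atol=1e-8)

    def test_variance_bookkeeping(self):
        rng = np.random.default_rng(4)
        x = rng.standard_normal((40, 12)) * np.linspace(4, 1, 12)
        atlas = build_pca(x)
        trace = np.trace(np.cov(x, rowvar=False, ddof=1))
        assert atlas.eigenvalues.sum() == pytest.approx(trace, rel=1e-8)
        assert atlas.variance_fractions.sum() == pytest.approx(1.0, abs=1e-10)
        cum = atlas.cumulative_variance
        assert np.all(np.diff(cum) >= -1e-12)

    def test_mode_sign_convention(self):
        rng = np.random.default_rng(5)
        x = rng.standard_normal((25, 8)) * np.linspace(3, 1, 8)
        atlas = build_pca(x)
        for k in range(atlas.modes.shape[1]):
            col = atlas.modes[:, k]
            assert col[np.argmax(np.abs(col))] > 0

    def test_score_variance_equals_eigenvalue(self):
        rng = np.random.default_rng(6)
        x = rng.standard_normal((50, 7)) * np.linspace(5, 1, 7)
        atlas = build_pca(x)
        scores = project(atlas, x, n_modes=atlas.modes.shape[1])
        np.testing.assert_allclose(scores.mean(axis=0), 0.0, atol=1e-8)
        np.testing.assert_allclose(scores.var(axis=0, ddof=1),
                                   atlas.eigenvalues, rtol=1e-6)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            build_pca(np.ones((5, 4)))


class TestFrames:
    def test_concatenate_and_split_roundtrip(self):
        rng = np.random.default_rng(7)
        ed, es = rng.standard_normal((9, 12)), rng.standard_normal((9, 12))
        both = concatenate_frames(ed, es)
        assert both.shape == (9, 24)
        back_ed, back_es = split_frames(both)
        np.testing.assert_array_equal(back_ed, ed)
        np.testing.assert_array_equal(back_es, es)

    def test_duplicated_frames_double_the_eigenvalues(self):
        """If ES equals ED for every case, the ED&ES eigenvalues are exactly
        twice the ED-only eigenvalues (block-duplicated covariance)."""
        rng = np.random.default_rng(8)
        ed = rng.standard_normal((15, 10)) * np.linspace(3, 1, 10)
        atlas_ed = build_pca(ed)
        atlas_both = build_pca(concatenate_frames(ed, ed))
        n = min(len(atlas_ed.eigenvalues), len(atlas_both.eigenvalues))
        np.testing.assert_allclose(atlas_both.eigenvalues[:n],
                                   2.0 * atlas_ed.eigenvalues[:n], rtol=1e-9)

    def test_mismatched_frames_rejected(self):
        with pytest.raises(ValueError, match="mismatch"):
            concatenate_frames(np.zeros((3, 4)), np.zeros((3, 5)))


class TestProjection:
    @pytest.fixture
    def atlas_and_data(self):
        rng = np.random.default_rng(9)
        x = rng.standard_normal((30, 12)) * np.linspace(4, 0.5, 12) + 7.0
        return build_pca(x), x

    def test_mean_shape_projects_to_zero(self, atlas_and_data):
        atlas, _ = atlas_and_data
        np.testing.assert_allclose(project(atlas, atlas.mean), 0.0, atol=1e-10)

    def test_full_rank_roundtrip(self, atlas_and_data):
        atlas, x = atlas_and_data
        m = atlas.modes.shape[1]
        scores = project(atlas, x[3], n_modes=m)
        np.testing.assert_allclose(reconstruct(atlas, scores), x[3], atol=1e-8)

    def test_truncation_error_satisfies_parseval(self, atlas_and_data):
        atlas, x = atlas_and_data
        m = atlas.modes.shape[1]
        full = project(atlas, x[5], n_modes=m)
        kept = 4
        approx = reconstruct(atlas, full[:kept])
        err2 = float(np.sum((approx - x[5]) ** 2))
        assert err2 == pytest.approx(float(np.sum(full[kept:] ** 2)), rel=1e-8)

    def test_dimension_mismatch_rejected(self, atlas_and_data):
        atlas, _ = atlas_and_data
        with pytest.raises(ValueError, match="dimension"):
            project(atlas, np.zeros(atlas.n_dim + 1))


class TestModeExtremes:
    def test_zero_offset_is_mean_and_symmetry(self):
        rng = np.random.default_rng(10)
        x = rng.standard_normal((20, 6)) * np.linspace(3, 1, 6)
        atlas = build_pca(x)
        np.testing.assert_array_equal(mode_extreme_shape(atlas, 1, 0.0),
                                      atlas.mean)
        plus = mode_extreme_shape(atlas, 2, 2.0)
        minus = mode_extreme_shape(atlas, 2, -2.0)
        np.testing.assert_allclose(0.5 * (plus + minus), atlas.mean, atol=1e-10)

    def test_out_of_range_mode_rejected(self):
        rng = np.random.default_rng(11)
        atlas = build_pca(rng.standard_normal((10, 4)))
        with pytest.raises(ValueError, match="out of range"):
            mode_extreme_shape(atlas, 99, 1.0)

    def test_mode1_extremes_order_cavity_volume(self, small_run):
        """Moving +2 SD along mode 1 produces a larger cavity than -2 SD,
        operationalizing 'mode 1 is the size mode' geometrically."""
        from lvatlas.geometry import SurfacePointSet, cavity_volume

        atlas = small_run.atlases["ED"]
        grid = small_run.cohort.grid
        vols = {}
        for c in (+2.0, -2.0):
            vec = mode_extreme_shape(atlas, 1, c)
            s = SurfacePointSet(vec.reshape(-1, 3), grid, "ED")
            vols[c] = cavity_volume(s)
        assert vols[2.0] > vols[-2.0]


class TestInterpretation:
    def test_single_factor_cohort_pins_mode1(self):
        """When only the size factor varies, mode 1 correlates with it almost
        perfectly."""
        import lvatlas as lv
        from dataclasses import replace
        from tests.conftest import small_population

        cfg = small_population(n_control=40, n_patient=2, noise=0.05,
                               shape_field_amplitude=0.0)
        grp = cfg.control
        sds = {k: 0.0 for k in grp.latent_sds}
        sds["base_endo_radius"] = grp.latent_sds["base_endo_radius"]
        cfg = replace(cfg, control=replace(grp, latent_sds=sds))
        cohort = lv.generate_cohort(cfg)
        ctl = cohort.labels == 0
        x = cohort.shape_vectors("ED")[ctl]
        atlas = build_pca(x, store_modes="retained")
        scores = mode_scores_table(atlas, x)
        table = interpret_modes(scores, cohort.latents[ctl])
        assert table.iloc[0]["top_factor"] == "base_endo_radius"
        assert table.iloc[0]["base_endo_radius"] > 0.99

    def test_shuffled_latents_show_only_null_correlation(self, small_cohort):
        """Scores against independently shuffled latents: the largest |corr|
        is consistent with the 3/sqrt(n) null bound."""
        x = small_cohort.shape_vectors("ED")
        atlas = build_pca(x, store_modes="retained")
        scores = mode_scores_table(atlas, x).iloc[:, :3]
        rng = np.random.default_rng(123)
        shuffled = small_cohort.latents.sample(frac=1.0, random_state=99)
        table = interpret_modes(scores, shuffled.reset_index(drop=True))
        max_corr = table.drop(columns="top_factor").to_numpy().max()
        assert max_corr < 3.0 / np.sqrt(small_cohort.n_cases)

    def test_missing_latents_rejected(self):
        with pytest.raises(ValueError, match="latent"):
            interpret_modes(pd.DataFrame({"mode1": [1.0, 2.0]}), None)
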