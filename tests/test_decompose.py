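"""PCA, CCA, ICA rotation, variable loadings and the composed pipeline."""

import numpy as np
import pytest
from scipy import stats
from scipy.linalg import subspace_angles

from conftest import cca_oracle, center
from neuromodes.blocks import DataBlock
from neuromodes.decompose import (DecompositionConfig, compute_variable_loadings,
                                  fit_cca, fit_ica_rotation, fit_pca,
                                  run_full_decomposition)
from neuromodes.simulate import generate_linked_blocks


class TestFitPCA:
    def test_rank_one_block_explains_everything(self):
        rng = np.random.default_rng(0)
        col = rng.standard_normal(20)
        X = np.column_stack([col, col, col])
        res = fit_pca(X, 1)
        total = ((X - X.mean(0)) ** 2).sum() / 19
        assert res.explained_variance[0] == pytest.approx(total, rel=1e-10)

    def test_full_basis_reconstructs_centered_data(self):
        rng = np.random.default_rng(1)
        X = rng.standard_normal((15, 6))
        res = fit_pca(X, 6)
        Xc = X - X.mean(0)
        np.testing.assert_allclose(res.scores @ res.basis.T, Xc, atol=1e-8)

    def test_basis_is_orthonormal(self):
        rng = np.random.default_rng(2)
        res = fit_pca(rng.standard_normal((30, 8)), 5)
        np.testing.assert_allclose(res.basis.T @ res.basis, np.eye(5), atol=1e-8)

    def test_explained_variance_matches_covariance_eigensolve(self):
        rng = np.random.default_rng(3)
        X = rng.standard_normal((30, 8))
        res = fit_pca(X, 8)
        Xc = X - X.mean(0)
        evals = np.sort(np.linalg.eigvalsh(Xc.T @ Xc / 29))[::-1]
        np.testing.assert_allclose(res.explained_variance, evals, atol=1e-10)

    def test_overlarge_n_comp_reports_attainable_rank(self):
        rng = np.random.default_rng(4)
        col = rng.standard_normal(10)
        X = np.column_stack([col, 2 * col, 3 * col])
        with pytest.raises(ValueError, match="rank"):
            fit_pca(X, 2)


class TestFitCCA:
    def test_identical_blocks_give_unit_correlations(self):
        rng = np.random.default_rng(5)
        X = rng.standard_normal((40, 4))
        res = fit_cca(X, X.copy(), 4)
        np.testing.assert_allclose(res.canonical_corrs, 1.0, atol=1e-10)

    def test_one_dimensional_case_equals_absolute_pearson(self):
        x = np.array([[1.0], [2.0], [3.0], [4.0]])
        y = np.array([[2.0], [4.0], [5.0], [9.0]])
        res = fit_cca(x, y, 1)
        expected = abs(stats.pearsonr(x[:, 0], y[:, 0]).statistic)
        assert res.canonical_corrs[0] == pytest.approx(expected, abs=1e-12)

    def test_orthogonal_vectors_give_zero_correlation(self):
        x = np.array([[1.0], [-1.0], [1.0], [-1.0]])
        y = np.array([[1.0], [1.0], [-1.0], [-1.0]])
        res = fit_cca(x, y, 1)
        assert res.canonical_corrs[0] == pytest.approx(0.0, abs=1e-10)

    def test_matches_generalized_eigenproblem_oracle(self):
        rng = np.random.default_rng(6)
        for _ in range(5):
            X = rng.standard_normal((50, 5))
            Y = rng.standard_normal((50, 4))
            mine = fit_cca(X, Y, 4).canonical_corrs
            np.testing.assert_allclose(mine, cca_oracle(X, Y), atol=1e-8)

    def test_matches_sklearn_cross_decomposition(self):
        # independent library route for the leading canonical pair
        from sklearn.cross_decomposition import CCA as SkCCA
        rng = np.random.default_rng(7)
        X = rng.standard_normal((60, 5))
        Y = rng.standard_normal((60, 4))
        mine = fit_cca(X, Y, 1)
        sk = SkCCA(n_components=1, scale=True, max_iter=2000).fit(X, Y)
        xs, ys = sk.transform(X, Y)
        r = abs(stats.pearsonr(xs[:, 0], ys[:, 0]).statistic)
        assert mine.canonical_corrs[0] == pytest.approx(r, abs=1e-6)

    def test_variates_have_stated_invariants(self):
        rng = np.random.default_rng(8)
        X = rng.standard_normal((80, 6))
        Y = rng.standard_normal((80, 5))
        res = fit_cca(X, Y, 4)
        for k in range(4):
            r = stats.pearsonr(res.U[:, k], res.V[:, k]).statistic
            assert r == pytest.approx(res.canonical_corrs[k], abs=1e-8)
        corr_u = np.corrcoef(res.U.T)
        np.testing.assert_allclose(corr_u, np.eye(4), atol=1e-6)
        assert (np.diff(res.canonical_corrs) <= 1e-12).all()

    def test_zero_variance_column_rejected(self):
        X = np.ones((10, 2))
        with pytest.raises(ValueError, match="zero-variance"):
            fit_cca(X, np.random.default_rng(9).standard_normal((10, 2)), 1)


class TestICARotation:
    def test_one_mode_rotation_is_trivial(self):
        rng = np.random.default_rng(10)
        X = rng.standard_normal((100, 3))
        Y = 0.5 * X + rng.standard_normal((100, 3))
        cca = fit_cca(X, Y, 1)
        modes = fit_ica_rotation(cca, 1, seed=0)
        assert abs(abs(modes.unmixing[0, 0]) - 1.0) < 1e-12
        assert modes.mode_corrs[0] == pytest.approx(cca.canonical_corrs[0],
                                                    abs=1e-10)

    def test_unmixing_orthonormal_on_whitened_scores(self):
        rng = np.random.default_rng(11)
        X = rng.laplace(size=(300, 4))
        Y = 0.7 * X + rng.laplace(size=(300, 4))
        cca = fit_cca(X, Y, 3)
        modes = fit_ica_rotation(cca, 3, seed=1)
        # M = whiten @ W.T with W orthonormal; so M^T C M = I where C is the
        # stacked-score covariance (the whitened-space orthonormality claim)
        stacked = np.vstack([cca.U[:, :3], cca.V[:, :3]])
        stacked -= stacked.mean(0)
        C = stacked.T @ stacked / (stacked.shape[0] - 1)
        np.testing.assert_allclose(modes.unmixing.T @ C @ modes.unmixing,
                                   np.eye(3), atol=1e-6)

    def test_matches_sklearn_fastica_sources(self):
        # independent implementation route: sklearn's FastICA on the same
        # whitened data must find the same sources up to sign/permutation
        from sklearn.decomposition import FastICA
        from neuromodes.decompose import symmetric_fastica
        rng = np.random.default_rng(40)
        S_true = rng.laplace(size=(3000, 2))
        A = np.array([[1.0, 0.7], [-0.3, 1.2]])
        X = S_true @ A.T
        Xc = X - X.mean(0)
        C = Xc.T @ Xc / (len(Xc) - 1)
        ev, E = np.linalg.eigh(C)
        Z = Xc @ (E @ np.diag(ev ** -0.5) @ E.T)
        W_mine, conv = symmetric_fastica(Z, rng.standard_normal((2, 2)))
        assert conv
        sk = FastICA(whiten=False, fun="logcosh", max_iter=500, tol=1e-7,
                     w_init=rng.standard_normal((2, 2))).fit(Z)
        S_mine = Z @ W_mine.T
        S_sk = sk.transform(Z)
        cross = np.abs(np.corrcoef(S_mine.T, S_sk.T)[:2, 2:])
        # each of my sources matches exactly one sklearn source
        assert np.allclose(np.sort(cross.max(axis=1)), 1.0, atol=1e-3)

    def test_recovers_planted_nongaussian_sources(self):
        # mix two independent Laplace factors into both sides; ICA must undo
        # the in-subspace mixing up to sign/permutation
        rng = np.random.default_rng(12)
        n = 2000
        s = rng.laplace(size=(n, 2))
        mix = np.array([[0.8, 0.6], [-0.6, 0.8]]) @ np.array([[1.0, 0.4], [0.0, 1.0]])
        Ux = s @ mix.T
        X = np.column_stack([Ux, 0.01 * rng.standard_normal((n, 2))])
        Y = np.column_stack([Ux + 0.05 * rng.standard_normal((n, 2)),
                             0.01 * rng.standard_normal((n, 2))])
        cca = fit_cca(X, Y, 2)
        modes = fit_ica_rotation(cca, 2, seed=3)
        for k in range(2):
            rs = [abs(np.corrcoef(modes.brain_mode_loadings[:, k], s[:, j])[0, 1])
                  for j in range(2)]
            assert max(rs) >= 0.99


class TestVariableLoadings:
    def _modes(self, small_linked):
        brain, behav, _, _ = small_linked
        return (center(brain), center(behav),
                run_full_decomposition(center(brain), center(behav),
                                       DecompositionConfig(15, 15, 2, seed=2)))

    def test_variable_equal_to_loadings_correlates_perfectly(self, small_linked):
        brain, behav, modes = self._modes(small_linked)
        spiked = behav.values.copy()
        spiked[:, 0] = modes.behav_mode_loadings[:, 0]
        block = DataBlock(spiked, behav.participant_ids, behav.variable_names)
        vl = compute_variable_loadings(modes, brain, block)
        row = vl[(vl["variable"] == "behav_001") & (vl["mode"] == 1)]
        assert row["loading"].iloc[0] == pytest.approx(1.0, abs=1e-10)

    def test_orthogonal_covariate_leaves_loadings_unchanged(self, small_linked):
        from neuromodes.blocks import ConfoundTable
        import pandas as pd
        brain, behav, modes = self._modes(small_linked)
        n = brain.n_participants
        base = compute_variable_loadings(modes, brain, behav)
        # covariate orthogonal (by construction) to loadings and variables
        cov = np.ones(n)
        cov[: n // 2] = -1.0
        stack = np.column_stack([modes.brain_mode_loadings,
                                 modes.behav_mode_loadings,
                                 brain.values, behav.values])
        beta, *_ = np.linalg.lstsq(stack, cov, rcond=None)
        cov_orth = cov - stack @ beta
        conf = ConfoundTable(pd.DataFrame({"c": cov_orth},
                                          index=brain.participant_ids),
                             continuous=["c"])
        part = compute_variable_loadings(modes, brain, behav,
                                         covariates_to_partial=["c"],
                                         confounds=conf)
        np.testing.assert_allclose(part["loading"], base["loading"], atol=1e-10)

    def test_partial_correlation_matches_textbook_formula(self, small_linked):
        from neuromodes.blocks import ConfoundTable
        import pandas as pd
        brain, behav, modes = self._modes(small_linked)
        idx = np.arange(12)
        rng = np.random.default_rng(13)
        zc = rng.standard_normal(12)
        b12 = DataBlock(brain.values[idx], [brain.participant_ids[i] for i in idx],
                        brain.variable_names)
        v12 = DataBlock(behav.values[idx], b12.participant_ids, behav.variable_names)
        m12 = type(modes)(modes.unmixing, modes.brain_mode_loadings[idx],
                          modes.behav_mode_loadings[idx], modes.mode_corrs,
                          modes.brain_projection, modes.behav_projection,
                          modes.brain_mean, modes.behav_mean,
                          modes.brain_variables, modes.behav_variables,
                          b12.participant_ids)
        conf = ConfoundTable(pd.DataFrame({"z": zc}, index=b12.participant_ids),
                             continuous=["z"])
        part = compute_variable_loadings(m12, b12, v12,
                                         covariates_to_partial=["z"],
                                         confounds=conf)
        x = m12.behav_mode_loadings[:, 0]
        y = v12.values[:, 3]
        rxy = stats.pearsonr(x, y).statistic
        rxz = stats.pearsonr(x, zc).statistic
        ryz = stats.pearsonr(y, zc).statistic
        expected = (rxy - rxz * ryz) / np.sqrt((1 - rxz ** 2) * (1 - ryz ** 2))
        row = part[(part["variable"] == "behav_004") & (part["mode"] == 1)]
        assert row["loading"].iloc[0] == pytest.approx(expected, abs=1e-10)

    def test_constant_variable_reports_nan_not_zero(self, small_linked):
        brain, behav, modes = self._modes(small_linked)
        flat = behav.values.copy()
        flat[:, 1] = 7.0
        block = DataBlock(flat, behav.participant_ids, behav.variable_names)
        vl = compute_variable_loadings(modes, brain, block)
        assert vl[(vl["variable"] == "behav_002")]["loading"].isna().all()


class TestFullDecomposition:
    def test_planted_modes_recovered(self, planted):
        corrs = np.sort(planted.modes.mode_corrs)[::-1]
        assert corrs[0] == pytest.approx(0.9, abs=0.05)
        assert corrs[1] == pytest.approx(0.7, abs=0.05)
        pairs = planted.match_to_truth(planted.modes.brain_mode_loadings,
                                       planted.truth.brain_factors[planted.train_idx])
        assert sorted(j for j, _ in pairs) == [0, 1]
        assert all(r >= 0.9 for _, r in pairs)

    def test_deterministic_given_config(self, small_linked):
        brain, behav, _, _ = small_linked
        cfg = DecompositionConfig(12, 12, 2, seed=5)
        a = run_full_decomposition(brain, behav, cfg)
        b = run_full_decomposition(brain, behav, cfg)
        np.testing.assert_array_equal(a.brain_mode_loadings, b.brain_mode_loadings)
        np.testing.assert_array_equal(a.unmixing, b.unmixing)

    def test_scale_and_variable_order_invariance(self, small_linked):
        brain, behav, _, _ = small_linked
        cfg = DecompositionConfig(12, 12, 2, seed=6)
        base = run_full_decomposition(brain, behav, cfg)
        scaled = DataBlock(3.5 * brain.values, brain.participant_ids,
                           brain.variable_names)
        perm = list(reversed(behav.variable_names))
        shuffled = behav.subset_variables(perm)
        alt = run_full_decomposition(scaled, shuffled, cfg)
        np.testing.assert_allclose(np.sort(alt.mode_corrs),
                                   np.sort(base.mode_corrs), atol=1e-8)

    def test_rotation_preserves_canonical_subspace(self, small_linked):
        brain, behav, _, _ = small_linked
        bc, vc = center(brain), center(behav)
        cfg = DecompositionConfig(12, 12, 2, seed=7)
        modes = run_full_decomposition(bc, vc, cfg)
        pca_b = fit_pca(bc, 12)
        pca_v = fit_pca(vc, 12)
        cca = fit_cca(pca_b.scores, pca_v.scores, 2)
        angles = subspace_angles(modes.brain_mode_loadings, cca.U)
        assert np.max(angles) < 1e-6

    def test_projection_composition_reproduces_loadings(self, planted):
        modes = planted.modes
        proj = planted.brain_train.values @ modes.brain_projection
        np.testing.assert_allclose(proj, modes.brain_mode_loadings, atol=1e-8)
        proj_v = planted.behav_train.values @ modes.behav_projection
        np.testing.assert_allclose(proj_v, modes.behav_mode_loadings, atol=1e-8)

    def test_sign_convention_top_behaviour_loading_positive(self, planted):
        vl = planted.modes.variable_loadings
        for k in range(2):
            sub = vl[(vl["mode"] == k + 1) & (vl["block"] == "behaviour")]
            assert sub.loc[sub["loading"].abs().idxmax(), "loading"] > 0

    def test_independent_blocks_stay_below_permutation_null(self):
        from neuromodes.inference import permutation_test_modes
        rng = np.random.default_rng(14)
        n = 500
        brain = DataBlock(rng.standard_normal((n, 20)),
                          [f"p{i}" for i in range(n)],
                          [f"b{j}" for j in range(20)])
        behav = DataBlock(rng.standard_normal((n, 20)),
                          [f"p{i}" for i in range(n)],
                          [f"v{j}" for j in range(20)])
        cfg = DecompositionConfig(10, 10, 2, seed=15)
        rep = permutation_test_modes(brain, behav, cfg, n_perm=199, seed=16)
        assert rep.observed.max() < np.percentile(rep.null_max, 95)

    def test_stage_errors_carry_stage_name(self, small_linked):
        brain, behav, _, _ = small_linked
        cfg = DecompositionConfig(n_comp_brain=5, n_comp_behav=5,
                                  n_modes=8, seed=0)
        with pytest.raises(ValueError, match=r"\[cca\]"):
            run_full_decomposition(brain, behav, cfg)
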