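"""Canonical decomposition, permutation inference, stability, pain scores."""

import numpy as np
import pandas as pd
import pytest

import painprofiles as pp
from conftest import make_feature_table


class TestFit:
    def test_duplicated_view_gives_perfect_first_mode(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(60, 5))
        model = pp.fit_pls(X, X.copy(), K=2)
        assert model.R[0] == pytest.approx(1.0, abs=1e-8)
        c = abs(np.corrcoef(model.U[:, 0], model.V[:, 0])[0, 1])
        assert c == pytest.approx(1.0, abs=1e-6)

    def test_independent_noise_modes_near_zero(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(4000, 6))
        Y = rng.normal(size=(4000, 8))
        model = pp.fit_pls(X, Y, K=3)
        assert np.abs(model.R).max() < 0.12

    def test_matches_sklearn_plscanonical_first_mode(self):
        """Independent cross-check of the leading mode against the reference
        canonical-PLS implementation."""
        from sklearn.cross_decomposition import PLSCanonical

        rng = np.random.default_rng(5)
        Z = rng.normal(size=(300, 2))
        X = Z @ rng.normal(size=(2, 7)) + 0.5 * rng.normal(size=(300, 7))
        Y = Z @ rng.normal(size=(2, 9)) + 0.5 * rng.normal(size=(300, 9))
        ours = pp.fit_pls(X, Y, K=2)
        ref = PLSCanonical(n_components=2, scale=False).fit(X, Y)
        for k in range(2):
            cu = abs(np.corrcoef(ours.U[:, k], ref.y_weights_[:, k])[0, 1])
            cv = abs(np.corrcoef(ours.V[:, k], ref.x_weights_[:, k])[0, 1])
            assert cu > 0.999 and cv > 0.999

    def test_recovery_of_planted_vectors_exact_linear_model(self):
        """On directly constructed low-rank two-view data (no coding layer),
        the fitted vectors match the planted ones almost exactly."""
        rng = np.random.default_rng(9)
        n, p, q, K = 4000, 30, 40, 4
        U, _ = np.linalg.qr(rng.normal(size=(q, K)))
        V, _ = np.linalg.qr(rng.normal(size=(p, K)))
        S = np.diag([1.0, 0.85, 0.7, 0.55])
        Z = rng.normal(size=(n, K))
        X = Z @ S @ V.T + 0.05 * rng.normal(size=(n, p))
        Y = Z @ S @ U.T + 0.05 * rng.normal(size=(n, q))
        model = pp.fit_pls(X, Y, K=K)
        order, _ = pp.align_modes(U, model.U)
        for k in range(K):
            assert abs(np.corrcoef(U[:, k], model.U[:, order[k]])[0, 1]) > 0.99
            assert abs(np.corrcoef(V[:, k], model.V[:, order[k]])[0, 1]) > 0.99

    def test_recovery_of_planted_vectors_through_generator(self):
        """Through the full observation model (0-10 standardisation of each
        feature), low-noise recovery clears the 0.9 bar per mode."""
        cfg = pp.GeneratorConfig(
            n_participants=6000, noise_sd=0.05, discrete_coding=False,
            frac_participants_heavy_missing=0.0, frac_fields_heavy_missing=0.0,
            frac_cell_missing=0.0, seed=9,
        )
        b = pp.generate_cohort(cfg)
        pain, _ = pp.recode(b.pain_table, pp.default_rules())
        model = pp.fit_pls(b.brain_table, pain, K=4)
        order, _ = pp.align_modes(b.ground_truth.true_U, model.U)
        for k in range(4):
            c = abs(np.corrcoef(b.ground_truth.true_U[:, k], model.U[:, order[k]])[0, 1])
            assert c > 0.9

    def test_deflation_exhausts_cross_covariance(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(30, 4))
        Y = rng.normal(size=(30, 6))
        model = pp.fit_pls(X, Y, K=4)
        # reconstruct residual by deflating with the fitted scores
        Xr = X - X.mean(0)
        Yr = Y - Y.mean(0)
        for l in range(4):
            t = Xr @ model.V[:, l]
            s = Yr @ model.U[:, l]
            Xr = Xr - np.outer(t, t @ Xr) / (t @ t)
            Yr = Yr - np.outer(s, s @ Yr) / (s @ s)
        assert np.linalg.norm(Xr.T @ Yr) < 1e-8

    def test_participant_permutation_invariance(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(50, 5))
        Y = rng.normal(size=(50, 7))
        perm = rng.permutation(50)
        a = pp.fit_pls(X, Y, K=3)
        b = pp.fit_pls(X[perm], Y[perm], K=3)
        np.testing.assert_allclose(a.U, b.U, atol=1e-10)
        np.testing.assert_allclose(a.V, b.V, atol=1e-10)
        np.testing.assert_allclose(a.R, b.R, atol=1e-10)

    def test_joint_sign_flip_leaves_r_unchanged(self):
        rng = np.random.default_rng(4)
        X = rng.normal(size=(40, 4))
        Y = rng.normal(size=(40, 5))
        model = pp.fit_pls(X, Y, K=2)
        t = (X - model.x_mean) @ (-model.V[:, 0])
        s = (Y - model.y_mean) @ (-model.U[:, 0])
        r_flipped = np.corrcoef(t, s)[0, 1]
        t0 = (X - model.x_mean) @ model.V[:, 0]
        s0 = (Y - model.y_mean) @ model.U[:, 0]
        assert r_flipped == pytest.approx(np.corrcoef(t0, s0)[0, 1], abs=1e-12)

    def test_errors(self):
        rng = np.random.default_rng(5)
        X = rng.normal(size=(20, 3))
        Y = rng.normal(size=(20, 4))
        with pytest.raises(ValueError, match="K="):
            pp.fit_pls(X, Y, K=5)
        Xz = X.copy()
        Xz[:, 1] = 2.0
        with pytest.raises(ValueError, match="zero-variance"):
            pp.fit_pls(Xz, Y, K=2)
        Xn = X.copy()
        Xn[0, 0] = np.nan
        with pytest.raises(ValueError, match="complete"):
            pp.fit_pls(Xn, Y, K=2)


class TestPermutationNull:
    def test_seeded_null_reproducible(self):
        rng = np.random.default_rng(6)
        X = rng.normal(size=(80, 4))
        Y = rng.normal(size=(80, 5))
        model = pp.fit_pls(X, Y, K=2)
        with pytest.warns(UserWarning, match="unstable"):
            a = pp.permutation_null(X, Y, model, n_perms=30, seed=11)
            b = pp.permutation_null(X, Y, model, n_perms=30, seed=11)
        np.testing.assert_array_equal(a.null_R, b.null_R)

    def test_planted_mode_beats_every_null_draw(self, midsize_prepared, midsize_model):
        _, pain, brain = midsize_prepared
        null = pp.permutation_null(brain, pain, midsize_model, n_perms=100, seed=2)
        pv = pp.mode_pvalues(midsize_model.R, null)
        assert np.allclose(pv["p_value"].iloc[:4], 1 / 101)

    def test_mode_pvalues_match_hand_count(self):
        null = pp.PermutationNull(
            null_R=np.array([[0.1], [0.2], [0.3], [0.4], [0.5]] * 4),
            null_U=np.zeros((20, 1, 1)),
            null_V=np.zeros((20, 1, 1)),
            n_perms=20,
            perm_seed=0,
        )
        # observed 0.35 -> 8 of 20 nulls >= 0.35 -> (1+8)/21
        pv = pp.mode_pvalues(np.array([0.35]), null)
        assert pv["p_value"].iloc[0] == pytest.approx(9 / 21)
        # observed below every draw -> p = 1
        pv_low = pp.mode_pvalues(np.array([0.05]), null)
        assert pv_low["p_value"].iloc[0] == pytest.approx(1.0)
        # observed above every draw -> add-one minimum
        pv_high = pp.mode_pvalues(np.array([0.9]), null)
        assert pv_high["p_value"].iloc[0] == pytest.approx(1 / 21)


class TestLoadings:
    def test_flags_match_quantile_oracle(self):
        rng = np.random.default_rng(7)
        n_perms, q = 40, 6
        null_U = rng.normal(size=(n_perms, q, 2))
        model = pp.PLSModel(
            V=np.zeros((3, 2)), U=rng.normal(size=(q, 2)), R=np.array([0.5, 0.4]),
            x_mean=np.zeros(3), y_mean=np.zeros(q), K=2,
            x_names=list("abc"), y_names=list("uvwxyz"),
        )
        null = pp.PermutationNull(
            null_R=np.zeros((n_perms, 2)), null_U=null_U,
            null_V=np.zeros((n_perms, 3, 2)), n_perms=n_perms, perm_seed=0,
        )
        flags = pp.significant_loadings(model, null, mode=1, tail=0.05)
        for j in range(q):
            thr = np.quantile(np.abs(null_U[:, j, 1]), 0.95)
            assert flags["significant"].iloc[j] == (abs(model.U[j, 1]) > thr)

    def test_zero_weight_never_flagged(self):
        model = pp.PLSModel(
            V=np.zeros((2, 1)), U=np.zeros((3, 1)), R=np.array([0.1]),
            x_mean=np.zeros(2), y_mean=np.zeros(3), K=1,
            x_names=["a", "b"], y_names=["u", "v", "w"],
        )
        null = pp.PermutationNull(
            null_R=np.zeros((50, 1)),
            null_U=np.abs(np.random.default_rng(0).normal(size=(50, 3, 1))),
            null_V=np.zeros((50, 2, 1)), n_perms=50, perm_seed=0,
        )
        flags = pp.significant_loadings(model, null, mode=0)
        assert not flags["significant"].any()

    def test_planted_domain_features_flagged(self, midsize_prepared, midsize_model):
        b, pain, brain = midsize_prepared
        null = pp.permutation_null(brain, pain, midsize_model, n_perms=100, seed=2)
        order, _ = pp.align_modes(
            b.ground_truth.true_U[[list(b.pain_table.features).index(f) for f in pain.features]],
            midsize_model.U,
        )
        flags = pp.significant_loadings(midsize_model, null, mode=int(order[0]))
        dominant = (pain.meta["domain"] == "pain-interference").to_numpy()
        assert flags["significant"].to_numpy()[dominant].mean() >= 0.8

    def test_domain_summary_arithmetic_and_dominance(self):
        loadings = pd.DataFrame(
            {
                "weight": [0.5, -0.2, 0.1, 0.4, -0.3],
                "significant": [True, True, False, True, True],
            },
            index=pd.Index(list("abcde"), name="feature"),
        )
        domains = pd.Series(
            ["d1", "d1", "d1", "d2", "d2"], index=list("abcde")
        )
        summary = pp.domain_summary(loadings, domains)
        assert summary.loc["d1", "n_significant"] == 2
        assert summary.loc["d1", "summed_weight"] == pytest.approx(0.3)
        assert summary.loc["d2", "summed_weight"] == pytest.approx(0.1)
        assert summary.attrs["dominant_domain"] == "d1"
        none = pp.domain_summary(loadings.assign(significant=False), domains)
        assert (none["n_significant"] == 0).all()
        assert (none["summed_weight"] == 0).all()


class TestSplitHalf:
    def test_planted_cohort_stable(self):
        cfg = pp.GeneratorConfig(
            n_participants=3000, noise_sd=0.1, discrete_coding=False,
            frac_participants_heavy_missing=0.0, frac_fields_heavy_missing=0.0,
            frac_cell_missing=0.0, seed=15,
        )
        b = pp.generate_cohort(cfg)
        pain, _ = pp.recode(b.pain_table, pp.default_rules())
        stab = pp.split_half_stability(b.brain_table, pain, K=4, n_iters=10, seed=3)
        assert np.median(stab) > 0.95

    def test_null_cohort_unstable(self):
        rng = np.random.default_rng(8)
        q = 30
        X = rng.normal(size=(400, 20))
        Y = rng.normal(size=(400, q))
        stab = pp.split_half_stability(X, Y, K=2, n_iters=10, seed=3)
        # random unit vectors in q dims have mean |corr| ~ sqrt(2/(pi q))
        assert np.median(stab) < 4 * np.sqrt(2 / (np.pi * q))

    def test_deterministic_under_seed(self):
        rng = np.random.default_rng(9)
        X = rng.normal(size=(100, 5))
        Y = rng.normal(size=(100, 6))
        a = pp.split_half_stability(X, Y, K=2, n_iters=3, seed=1)
        b = pp.split_half_stability(X, Y, K=2, n_iters=3, seed=1)
        np.testing.assert_array_equal(a, b)


class TestPainScores:
    def test_mean_participant_scores_zero(self):
        rng = np.random.default_rng(10)
        X = rng.normal(size=(50, 4))
        Y = rng.normal(size=(50, 5))
        model = pp.fit_pls(X, Y, K=2)
        Y2 = np.vstack([Y, Y.mean(0)])
        model2 = pp.PLSModel(
            V=model.V, U=model.U, R=model.R, x_mean=model.x_mean,
            y_mean=Y.mean(0), K=2, x_names=model.x_names, y_names=model.y_names,
        )
        scores = pp.pain_scores(Y2, model2, [0, 1])
        np.testing.assert_allclose(scores.values[-1], 0.0, atol=1e-10)

    def test_matches_matrix_product_toy(self):
        Y = np.arange(12.0).reshape(3, 4)
        U = np.array([[1.0, 0], [0, 1], [0, 0], [0, 0]])
        model = pp.PLSModel(
            V=np.zeros((2, 2)), U=U, R=np.zeros(2),
            x_mean=np.zeros(2), y_mean=Y.mean(0), K=2,
            x_names=["a", "b"], y_names=[0, 1, 2, 3],
        )
        scores = pp.pain_scores(Y, model, [0, 1])
        np.testing.assert_allclose(scores.values, (Y - Y.mean(0)) @ U)

    def test_feature_mismatch_raises(self, midsize_model):
        Y = pd.DataFrame(np.zeros((3, 2)), columns=["x", "y"])
        with pytest.raises(ValueError, match="do not match"):
            pp.pain_scores(Y, midsize_model, [0])

    def test_high_latent_participants_rank_high(self, midsize_prepared, midsize_model):
        b, pain, brain = midsize_prepared
        keep = [list(b.pain_table.features).index(f) for f in pain.features]
        order, signs = pp.align_modes(b.ground_truth.true_U[keep], midsize_model.U)
        scores = pp.pain_scores(pain, midsize_model, [int(order[0])])
        z1 = pd.Series(
            b.ground_truth.latent_scores[:, 0], index=b.pain_table.participant_ids
        ).loc[scores.scores.index]
        s = signs[0] * scores.values[:, 0]
        top_latent = z1 >= z1.quantile(0.9)
        assert pd.Series(s, index=scores.scores.index)[top_latent].mean() > np.median(s)
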