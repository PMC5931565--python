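import numpy as np
import pandas as pd
import pytest

from gallop import (
    LongitudinalLMM,
    SimulationConfig,
    VarianceComponents,
    assemble,
    fit_variance_components,
    henderson_solve,
    precompute,
    rotate,
    simulate_dataset,
    subject_blocks,
)


class TestRotation:
    def test_identity_block_gives_orthogonal_phi(self):
        Phi, U, om = rotate(np.zeros((2, 2)), np.eye(2))
        np.testing.assert_allclose(Phi @ Phi.T, np.eye(2), atol=1e-12)

    def test_diagonal_block(self):
        # S + P* = diag(4, 9): |Phi| entries are {1/2, 1/3} up to sign/order
        Phi, _, om = rotate(np.diag([3.0, 8.0]), np.eye(2))
        np.testing.assert_allclose(sorted(np.abs(Phi[Phi != 0])), [1 / 3, 1 / 2])
        np.testing.assert_allclose(
            Phi @ np.diag([4.0, 9.0]) @ Phi.T, np.eye(2), atol=1e-12
        )

    def test_whitening_identity_random_pd(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            B = rng.normal(size=(2, 2))
            S = B @ B.T
            P = np.eye(2) * rng.uniform(0.1, 5.0)
            Phi, _, _ = rotate(S, P)
            err = np.abs(Phi @ (S + P) @ Phi.T - np.eye(2)).max()
            assert err < 1e-10

    def test_non_pd_raises(self):
        with pytest.raises(ValueError, match="positive definite"):
            rotate(np.diag([1.0, 1.0]), -3 * np.eye(2))

    def test_batched_matches_single(self):
        rng = np.random.default_rng(8)
        S = np.einsum("nij,nkj->nik", *(2 * [rng.normal(size=(5, 2, 2))]))
        P = np.eye(2)
        Phi_b, _, _ = rotate(S, P)
        for i in range(5):
            Phi_i, _, _ = rotate(S[i], P)
            np.testing.assert_allclose(np.abs(Phi_b[i]), np.abs(Phi_i), atol=1e-12)


class TestVarianceComponents:
    def test_p_star_is_inverse_of_scaled_d(self):
        vc = VarianceComponents(D=[[1.0, -0.2], [-0.2, 1.0]], sigma2=6.25)
        np.testing.assert_allclose(
            vc.P_star @ (vc.D / vc.sigma2), np.eye(2), atol=1e-12
        )

    @pytest.mark.parametrize(
        "D,s2",
        [([[1.0, 0.0], [0.0, -1.0]], 1.0), ([[1.0, 0.5], [0.4, 1.0]], 1.0),
         ([[1.0, 0.0], [0.0, 1.0]], 0.0)],
    )
    def test_invalid_components_rejected(self, D, s2):
        with pytest.raises(ValueError):
            VarianceComponents(D=D, sigma2=s2)


class TestHenderson:
    def test_toy_system_matches_dense_inversion(self):
        # 3 subjects x 2 rows, hand-buildable sums
        rng = np.random.default_rng(2)
        t = np.array([0.0, 1.0, 0.0, 2.0, 1.0, 3.0])
        groups = np.array([0, 0, 1, 1, 2, 2])
        y = rng.normal(size=6)
        X = np.column_stack([np.ones(6), t])
        Z = X.copy()
        P = np.array([[2.0, 0.5], [0.5, 1.5]])
        sol = henderson_solve(X, Z, groups, P, y)

        # independent brute force: build the (p + 2n) square matrix directly
        Zfull = np.zeros((6, 6))
        for i in range(3):
            rows = groups == i
            Zfull[rows, 2 * i : 2 * i + 2] = Z[rows]
        H = np.block(
            [[X.T @ X, X.T @ Zfull], [Zfull.T @ X, Zfull.T @ Zfull + np.kron(np.eye(3), P)]]
        )
        rhs = np.concatenate([X.T @ y, Zfull.T @ y])
        full = np.linalg.solve(H, rhs)
        np.testing.assert_allclose(sol.beta, full[:2], atol=1e-10)
        np.testing.assert_allclose(sol.b.ravel(), full[2:], atol=1e-10)
        np.testing.assert_allclose(
            sol.cov_beta, np.linalg.inv(H)[:2, :2], atol=1e-10
        )

    def test_huge_penalty_reduces_to_weighted_least_squares(self):
        rng = np.random.default_rng(3)
        n, k = 10, 3
        t = rng.uniform(0, 5, n * k)
        groups = np.repeat(np.arange(n), k)
        X = np.column_stack([np.ones(n * k), t, rng.normal(size=n * k)])
        y = rng.normal(size=n * k)
        w = rng.integers(0, 2, n * k).astype(float)
        w[::k] = 1.0  # keep every subject
        Z = np.column_stack([np.ones(n * k), t])
        sol = henderson_solve(X, Z, groups, 1e12 * np.eye(2), y, weights=w)
        beta_wls = np.linalg.lstsq(X * w[:, None], y * w, rcond=None)[0]
        np.testing.assert_allclose(sol.beta, beta_wls, atol=1e-6)
        assert np.abs(sol.b).max() < 1e-6

    def test_collinear_fixed_effects_named(self):
        t = np.tile([0.0, 1.0], 4)
        groups = np.repeat(np.arange(4), 2)
        X = np.column_stack([np.ones(8), t, 2 * t])  # column 2 = 2 x column 1
        Z = np.column_stack([np.ones(8), t])
        with pytest.raises(np.linalg.LinAlgError, match="collinear"):
            henderson_solve(X, Z, groups, np.eye(2), np.zeros(8))


class TestREML:
    def test_cross_library_agreement_with_statsmodels(self):
        """REML optimum agrees with an independent mixed-model routine."""
        sm = pytest.importorskip("statsmodels.api")
        cfg = SimulationConfig(n=200, k=4, q=2, seed=9)
        data, _, _ = simulate_dataset(cfg)
        res = LongitudinalLMM(data).fit()

        df = data.to_frame()
        exog = sm.add_constant(df[["time"] + data.covariate_names])
        md = sm.MixedLM(
            df["y"], exog, groups=df["id"],
            exog_re=sm.add_constant(df[["time"]]),
        )
        mf = md.fit(reml=True, method="lbfgs")
        D_sm = mf.cov_re.to_numpy()
        assert np.abs(res.vc.D - D_sm).max() / np.abs(D_sm).max() < 1e-4
        assert abs(res.vc.sigma2 - mf.scale) / mf.scale < 1e-4
        assert np.abs(res.params.to_numpy() - mf.fe_params.to_numpy()).max() < 1e-4

    def test_noise_free_limit_recovers_fixed_effects(self):
        """With b = 0 and tiny jitter, GLS collapses to the generating betas."""
        cfg = SimulationConfig(
            n=150, k=4, q=2, D=np.zeros((2, 2)), sigma=1e-6,
            beta_cov=np.array([0.5, -1.0]), seed=4,
        )
        data, _, truth = simulate_dataset(cfg)
        res = LongitudinalLMM(data).fit(on_boundary="ignore")
        expect = np.array([cfg.beta0, cfg.beta1, 0.5, -1.0])
        assert np.abs(res.params.to_numpy() - expect).max() < 1e-6
        assert res.vc.sigma2 == pytest.approx(1e-12, rel=0.2)

    def test_transformed_and_untransformed_systems_agree(self, small_fit):
        """The whitened solve equals direct block elimination of the raw system."""
        data, _, vc, reduced = small_fit
        blocks = subject_blocks(data)
        P = vc.P_star
        # raw elimination: beta* = (A11 - sum R'T R)^-1 (q1 - sum R'T r)
        T = np.linalg.inv(blocks.S + P)
        M = blocks.A11 - np.einsum("nip,nij,njq->pq", blocks.R, T, blocks.R)
        rhs = blocks.q1 - np.einsum("nip,nij,nj->p", blocks.R, T, blocks.r)
        beta_raw = np.linalg.solve(M, rhs)
        np.testing.assert_allclose(
            reduced.params.to_numpy(), beta_raw, rtol=1e-8, atol=1e-10
        )
        b_raw = np.einsum(
            "nij,nj->ni", T,
            blocks.r - np.einsum("nip,p->ni", blocks.R, beta_raw),
        )
        np.testing.assert_allclose(reduced.random_effects, b_raw, atol=1e-8)

    def test_reduced_fit_matches_henderson_oracle(self, small_fit):
        data, _, vc, reduced = small_fit
        sol = henderson_solve(
            data.X_star, data.Z, data.row_subject, vc.P_star,
            data.y_filled, data.w, sigma2=vc.sigma2,
        )
        np.testing.assert_allclose(
            reduced.params.to_numpy(), sol.beta, rtol=1e-8
        )
        np.testing.assert_allclose(reduced.random_effects, sol.b, atol=1e-8)
        np.testing.assert_allclose(
            reduced.bse.to_numpy(), np.sqrt(np.diag(sol.cov_beta)), rtol=1e-6
        )

    def test_single_observation_subjects_are_retained(self):
        """k_i = 1 leaves S_i singular but S_i + P* PD; the fit must cope."""
        cfg = SimulationConfig(n=120, k=3, q=0, seed=6)
        data, _, _ = simulate_dataset(cfg)
        df = data.to_frame()
        # truncate 30 subjects to a single occasion
        singles = data.subject_ids[:30]
        keep = ~(df["id"].isin(singles) & (df.groupby("id").cumcount() > 0))
        data1 = assemble(df[keep])
        assert data1.n_subjects == 120
        vc, red = fit_variance_components(data1)
        blocks = subject_blocks(data1)
        Phi, _, _ = rotate(blocks.S, vc.P_star)
        err = np.abs(Phi @ (blocks.S + vc.P_star) @ np.swapaxes(Phi, 1, 2) - np.eye(2))
        assert err.max() < 1e-10

    def test_too_few_slope_subjects_rejected(self):
        df = pd.DataFrame(
            {"id": [1, 2, 3], "time": [0.0, 1.0, 2.0], "y": [0.1, 0.2, 0.3]}
        )
        with pytest.raises(ValueError, match="random slope"):
            LongitudinalLMM(assemble(df))

    def test_summary_mentions_components(self, small_fit):
        _, _, _, reduced = small_fit
        text = reduced.summary()
        assert "sigma^2" in text and "REML" in text and "time" in text
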