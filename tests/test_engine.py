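import numpy as np
import pytest

from gallop import (
    DosageBlock,
    LongitudinalLMM,
    SimulationConfig,
    handle_missing_dosage,
    neglog10_pvalues,
    precompute,
    predict_variance_inflation,
    score_block,
    simulate_dataset,
    wald_pvalues,
)
from gallop.engine import STATUS_ALL_MISSING, STATUS_MONOMORPHIC, STATUS_SKIPPED

from conftest import dense_full_model_solve


class TestPrecompute:
    def test_a11_is_design_cross_product(self, small_fit, small_pc):
        data, _, vc, _ = small_fit
        Xw = data.X_star * data.w[:, None]
        np.testing.assert_allclose(
            small_pc.blocks.A11, Xw.T @ data.X_star, rtol=1e-12
        )

    def test_idempotent(self, small_fit, small_pc):
        data, _, vc, reduced = small_fit
        pc2 = precompute(data, vc, reduced)
        np.testing.assert_array_equal(small_pc.E, pc2.E)
        np.testing.assert_array_equal(small_pc.beta_star, pc2.beta_star)

    def test_permutation_invariance(self, small_fit):
        """Scrambling subject order permutes, but does not change, results."""
        from gallop import assemble

        data, block, vc, _ = small_fit
        rng = np.random.default_rng(0)
        perm_ids = data.subject_ids[rng.permutation(data.n_subjects)]
        rank = {sid: i for i, sid in enumerate(perm_ids)}
        df = data.to_frame()
        df2 = df.iloc[np.argsort(df["id"].map(rank), kind="stable")]
        data2 = assemble(df2, covariate_cols=data.covariate_names)
        assert list(data2.subject_ids) == list(perm_ids)

        pos = {sid: i for i, sid in enumerate(data.subject_ids)}
        reorder = np.array([pos[sid] for sid in perm_ids])
        block2 = DosageBlock(dosages=block.dosages[reorder], snp_ids=block.snp_ids)

        res1 = score_block(precompute(data, vc), block)
        res2 = score_block(precompute(data2, vc), block2)
        for a, b in zip(res1, res2):
            assert a.beta2 == pytest.approx(b.beta2, rel=1e-9)
            assert a.se3 == pytest.approx(b.se3, rel=1e-9)


class TestScoreBlock:
    def test_matches_dense_henderson_oracle(self, small_fit, small_pc):
        """The bordered 2x2 solve reproduces the full dense mixed-model solve."""
        data, block, vc, _ = small_fit
        results = score_block(small_pc, block)
        for j, r in enumerate(results):
            b2, b3, se2, se3 = dense_full_model_solve(data, vc, block.dosages[:, j])
            scale = max(abs(b2), abs(b3), se2, se3)
            assert abs(r.beta2 - b2) / scale < 1e-8
            assert abs(r.beta3 - b3) / scale < 1e-8
            assert abs(r.se2 - se2) / scale < 1e-8
            assert abs(r.se3 - se3) / scale < 1e-8

    def test_blocked_equals_one_at_a_time(self, small_fit, small_pc):
        _, block, _, _ = small_fit
        res_block = score_block(small_pc, block)
        res_loop = score_block(small_pc, block, method="loop")
        for a, b in zip(res_block, res_loop):
            for attr in ("beta2", "beta3", "se2", "se3"):
                va, vb = getattr(a, attr), getattr(b, attr)
                assert abs(va - vb) <= 1e-12 * max(1.0, abs(vb))

    def test_rotation_sign_convention_is_immaterial(self, small_fit, monkeypatch):
        """Flipping eigenvector signs leaves every SNP estimate unchanged."""
        import gallop.engine as eng

        data, block, vc, _ = small_fit
        base = score_block(precompute(data, vc), block)
        orig = eng.rotate

        def flipped(S, P):
            Phi, U, om = orig(S, P)
            return -Phi, -U, om

        monkeypatch.setattr(eng, "rotate", flipped)
        alt = score_block(precompute(data, vc), block)
        for a, b in zip(base, alt):
            assert abs(a.beta2 - b.beta2) < 1e-12 * max(1, abs(a.beta2))
            assert abs(a.beta3 - b.beta3) < 1e-12 * max(1, abs(a.beta3))

    def test_all_zero_dosage_flagged_not_scored(self, small_pc):
        block = DosageBlock(dosages=np.zeros((small_pc.n_subjects, 1)), snp_ids=["z"])
        (r,) = score_block(small_pc, block)
        assert r.status == STATUS_MONOMORPHIC
        assert np.isnan(r.beta2) and np.isnan(r.p3)

    def test_constant_nonzero_dosage_flagged(self, small_pc):
        block = DosageBlock(
            dosages=np.full((small_pc.n_subjects, 1), 1.3), snp_ids=["c"]
        )
        (r,) = score_block(small_pc, block)
        assert r.status == STATUS_MONOMORPHIC

    def test_allele_flip_symmetry(self, small_fit, small_pc):
        """Scoring 2 - s flips the effect signs and keeps the SEs."""
        _, block, _, _ = small_fit
        res = score_block(small_pc, block)
        flipped = DosageBlock(
            dosages=2.0 - block.dosages, snp_ids=block.snp_ids,
            subject_ids=block.subject_ids,
        )
        res_f = score_block(small_pc, flipped)
        for a, b in zip(res, res_f):
            assert a.beta2 == pytest.approx(-b.beta2, rel=1e-9)
            assert a.beta3 == pytest.approx(-b.beta3, rel=1e-9)
            assert a.se2 == pytest.approx(b.se2, rel=1e-9)
            assert a.se3 == pytest.approx(b.se3, rel=1e-9)

    def test_subject_order_mismatch_rejected(self, small_fit, small_pc):
        _, block, _, _ = small_fit
        bad = DosageBlock(
            dosages=block.dosages,
            snp_ids=block.snp_ids,
            subject_ids=np.arange(block.n_subjects),
        )
        with pytest.raises(ValueError, match="subject order"):
            score_block(small_pc, bad)


class TestWald:
    def test_null_point(self):
        z, p = wald_pvalues(0.0, 1.0)
        assert z == 0.0 and p == 1.0

    def test_normal_quantile(self):
        _, p = wald_pvalues(1.959964, 1.0)
        assert p == pytest.approx(0.05, abs=1e-6)

    def test_nonpositive_se_rejected(self):
        with pytest.raises(ValueError):
            wald_pvalues(1.0, 0.0)

    def test_neglog10_matches_p_at_moderate_z(self):
        z = np.array([0.5, 2.0, 5.0])
        _, p = wald_pvalues(z, np.ones(3))
        np.testing.assert_allclose(neglog10_pvalues(z), -np.log10(p), rtol=1e-10)

    def test_neglog10_finite_in_deep_tail(self):
        nlp = neglog10_pvalues(60.0)
        assert np.isfinite(nlp) and 700 < nlp < 800


class TestVarianceInflation:
    def test_null_effects_leave_d_unchanged(self):
        D = np.array([[1.0, -0.2], [-0.2, 1.0]])
        np.testing.assert_array_equal(predict_variance_inflation(D, 0, 0, 0.5), D)

    def test_direct_substitution(self):
        D = np.array([[1.0, -0.2], [-0.2, 1.0]])
        out = predict_variance_inflation(D, 1.0, 0.0, 0.5)
        np.testing.assert_allclose(out, [[1.5, -0.2], [-0.2, 1.0]])

    def test_reduced_fit_shows_predicted_inflation(self):
        """Omitting a strong SNP inflates D-hat by var(s) * beta beta'."""
        cfg = SimulationConfig(n=3000, k=4, q=0, seed=17)
        data, block, truth = simulate_dataset(cfg, snp_effects=(0.8, 0.8))
        res = LongitudinalLMM(data).fit()
        s = block.dosages[:, 0]
        expected = predict_variance_inflation(cfg.D, 0.8, 0.8, s.var())
        assert np.abs(res.vc.D - expected).max() < 0.12


class TestMissingDosage:
    def _block(self, n):
        rng = np.random.default_rng(12)
        d = rng.uniform(0, 2, size=(n, 3))
        d[0, 1] = np.nan
        d[:, 2] = np.nan
        return DosageBlock(dosages=d, snp_ids=["a", "b", "c"])

    def test_clean_block_unchanged(self):
        d = np.ones((4, 1)) * 0.5
        block = DosageBlock(dosages=d, snp_ids=["a"])
        out = handle_missing_dosage(block, "mean_impute")
        np.testing.assert_array_equal(out.dosages, d)
        assert out.imputed.tolist() == [0]

    def test_mean_impute_fills_observed_mean(self):
        block = self._block(10)
        out = handle_missing_dosage(block, "mean_impute")
        obs = block.dosages[1:, 1]
        assert out.dosages[0, 1] == pytest.approx(obs.mean())
        assert out.imputed[1] == 1
        assert out.unscored[2] == STATUS_ALL_MISSING

    def test_skip_marks_unscored(self):
        block = self._block(10)
        out = handle_missing_dosage(block, "skip")
        assert out.unscored[0] is None
        assert out.unscored[1] == STATUS_SKIPPED
        assert out.unscored[2] == STATUS_ALL_MISSING

    def test_imputed_snp_equals_oracle_on_imputed_dosages(self, small_fit, small_pc):
        data, block, vc, _ = small_fit
        d = block.dosages[:, :1].copy()
        d[3, 0] = np.nan
        res = score_block(
            small_pc,
            DosageBlock(dosages=d, snp_ids=["x"], subject_ids=block.subject_ids),
            missing_policy="mean_impute",
        )[0]
        d_imp = d.copy()
        d_imp[3, 0] = np.nanmean(d[:, 0])
        b2, b3, se2, se3 = dense_full_model_solve(data, vc, d_imp[:, 0])
        assert res.beta2 == pytest.approx(b2, rel=1e-8)
        assert res.se3 == pytest.approx(se3, rel=1e-8)
        assert res.n_imputed == 1 and res.n_used == data.n_subjects


def test_null_panel_type_one_error_in_binomial_band():
    """Null SNPs reject at the nominal 5% rate for both effects."""
    cfg = SimulationConfig(n=400, k=4, q=2, n_snps=2000, seed=23)
    data, block, _ = simulate_dataset(cfg)
    from gallop import fit_variance_components

    vc, _ = fit_variance_components(data)
    res = score_block(precompute(data, vc), block)
    p2 = np.array([r.p2 for r in res])
    p3 = np.array([r.p3 for r in res])
    half = 2.576 * np.sqrt(0.05 * 0.95 / 2000)
    assert abs((p2 < 0.05).mean() - 0.05) < half + 0.005
    assert abs((p3 < 0.05).mean() - 0.05) < half + 0.005
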