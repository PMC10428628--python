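"""Mixed-model samplers: closed-form oracles, adjustment, and G x E kernels."""

import numpy as np
import pandas as pd
import pytest

import maizegp as mg
from maizegp.bayes import (
    DegenerateDataError,
    bgge_predictions,
    bmtme_predictions,
    fit_bmtme,
)
from maizegp.panel import KinshipMatrix


class TestBlupOracle:
    def test_identity_kinship_is_ridge(self):
        rng = np.random.default_rng(0)
        y = rng.standard_normal(20)
        s2u, s2e = 2.0, 4.0
        beta, u = mg.blup_oracle(y, np.eye(20), (np.array([[s2u]]), np.array([[s2e]])))
        lam = s2e / s2u
        expect = (y - y.mean()) / (1 + lam) * 1.0
        # ridge closed form: u = (I + lambda I)^-1 (y - mean)
        np.testing.assert_allclose(u[:, 0], expect, atol=1e-8)

    def test_infinite_shrinkage_limit(self):
        rng = np.random.default_rng(1)
        y = rng.standard_normal(15)
        _, u = mg.blup_oracle(y, np.eye(15), (np.array([[1e-10]]), np.array([[1.0]])))
        np.testing.assert_allclose(u, 0.0, atol=1e-6)

    def test_three_line_hand_solved_system(self):
        # y = mu + u + e, A = I3, G0 = R0 = 1 => MME:
        # [ 3   1 1 1 ] [mu]   [ y. ]
        # [ 1   2 0 0 ] [u1] = [ y1 ]
        # [ 1   0 2 0 ] [u2]   [ y2 ]
        # [ 1   0 0 2 ] [u3]   [ y3 ]
        y = np.array([1.0, 2.0, 6.0])
        C = np.array(
            [[3, 1, 1, 1], [1, 2, 0, 0], [1, 0, 2, 0], [1, 0, 0, 2]], dtype=float
        )
        rhs = np.array([y.sum(), *y])
        sol = np.linalg.solve(C, rhs)
        beta, u = mg.blup_oracle(y, np.eye(3), (np.array([[1.0]]), np.array([[1.0]])))
        np.testing.assert_allclose(beta[0, 0], sol[0], atol=1e-10)
        np.testing.assert_allclose(u[:, 0], sol[1:], atol=1e-10)

    def test_rank_deficient_design_raises(self):
        y = np.arange(5.0)
        X = np.ones((5, 2))  # duplicated intercept
        with pytest.raises(np.linalg.LinAlgError, match="confounded"):
            mg.blup_oracle(y, np.eye(5), (np.eye(1), np.eye(1)), fixed_design=X)


class TestMCMCMixed:
    def test_fixed_variance_posterior_matches_mme(self, small_panel, small_phenotypes, small_grm):
        records, _ = small_phenotypes
        sub = records[records.trait.isin(["FF", "MF"])]
        G0 = np.diag([8.0, 8.0])
        R0 = np.diag([4.0, 4.0])
        samples = mg.fit_mcmc_mixed(
            sub,
            small_grm,
            ["FF", "MF"],
            mg.MCMCSettings(4000, 1000, 2, seed=3),
            environment="E1",
            fix_variance=(G0, R0),
        )
        wide = sub[sub.environment == "E1"].pivot(index="line", columns="trait", values="value")
        wide = wide.loc[samples.line_ids, ["FF", "MF"]]
        _, u_exact = mg.blup_oracle(wide.to_numpy(), small_grm.align(samples.line_ids), (G0, R0))
        dev = np.abs(samples.mean("u") - u_exact).max()
        assert dev <= 0.05 * wide.to_numpy().std()

    def test_unknown_trait_raises(self, small_phenotypes, small_grm):
        records, _ = small_phenotypes
        with pytest.raises(ValueError, match="unknown trait"):
            mg.fit_mcmc_mixed(records, small_grm, ["XX"], environment="E1")

    def test_zero_variance_response_flags_degenerate(self, small_grm, small_panel):
        rec = pd.DataFrame(
            {
                "line": small_panel.line_ids,
                "environment": "E1",
                "replicate": 1,
                "block": 1,
                "trait": "FF",
                "value": 5.0,
            }
        )
        with pytest.raises(DegenerateDataError):
            mg.fit_mcmc_mixed(rec, small_grm, ["FF"], mg.MCMCSettings.tiny())

    def test_draw_count_bookkeeping(self, small_phenotypes, small_grm):
        records, _ = small_phenotypes
        settings = mg.MCMCSettings(1000, 300, 7, seed=1)
        samples = mg.fit_mcmc_mixed(records, small_grm, ["FF"], settings, environment="E1")
        assert samples.n_draws == (1000 - 300) // 7 == settings.n_draws

    def test_seeded_chain_reproducible(self, small_phenotypes, small_grm, tiny_settings):
        records, _ = small_phenotypes
        a = mg.fit_mcmc_mixed(records, small_grm, ["FF"], tiny_settings, environment="E1")
        b = mg.fit_mcmc_mixed(records, small_grm, ["FF"], tiny_settings, environment="E1")
        np.testing.assert_array_equal(a.draws["u"], b.draws["u"])
        np.testing.assert_array_equal(a.draws["G0"], b.draws["G0"])

    def test_covariance_draws_symmetric_pd(self, small_phenotypes, small_grm, tiny_settings):
        records, _ = small_phenotypes
        s = mg.fit_mcmc_mixed(records, small_grm, ["FF", "MF"], tiny_settings, environment="E1")
        for name in ("G0", "R0"):
            for draw in s.draws[name][::50]:
                np.testing.assert_allclose(draw, draw.T, atol=1e-10)
                assert np.linalg.eigvalsh(draw).min() > 0


class TestGeneticCorrelation:
    def _samples(self, G0_draws):
        return mg.PosteriorSamples(
            model="mcmc_mixed",
            draws={"G0": np.asarray(G0_draws, dtype=float)},
            line_ids=[],
            trait_names=["FF", "MF"],
        )

    def test_perfect_correlation(self):
        s = self._samples([np.full((2, 2), 3.0)] * 10)
        mean, (lo, hi) = mg.genetic_correlation(s, "FF", "MF")
        assert mean == pytest.approx(1.0)

    def test_zero_covariance(self):
        s = self._samples([np.diag([2.0, 5.0])] * 10)
        mean, _ = mg.genetic_correlation(s, "FF", "MF")
        assert mean == pytest.approx(0.0)

    def test_absent_trait_raises(self):
        s = self._samples([np.eye(2)] * 4)
        with pytest.raises(ValueError):
            mg.genetic_correlation(s, "FF", "ASI")


class TestAdjustPhenotypes:
    def test_single_replicate_passthrough(self, small_phenotypes):
        records, _ = small_phenotypes  # generated with one replicate
        adjusted = mg.adjust_phenotypes(records)
        merged = adjusted.merge(
            records, on=["line", "environment", "trait"], suffixes=("_adj", "_raw")
        )
        np.testing.assert_allclose(merged.value_adj, merged.value_raw, atol=1e-12)

    def test_balanced_replicate_offset_cancels(self, small_panel):
        cfg = mg.TraitConfig(
            trait_names=("FF",), target_h2={"FF": 0.7}, asi_is_difference=False,
            replicate_sd=0.0, block_sd=0.0,
        )
        rec, _ = mg.simulate_phenotypes(
            small_panel, cfg, ("E1",), seed=5, n_replicates=2, n_blocks=1
        )
        delta = 7.5
        shifted = rec.copy()
        shifted.loc[shifted.replicate == 2, "value"] += delta
        base = mg.adjust_phenotypes(rec, mg.MCMCSettings(3000, 1000, 2, seed=9))
        moved = mg.adjust_phenotypes(shifted, mg.MCMCSettings(3000, 1000, 2, seed=9))
        d_base = base.value.to_numpy() - base.value.mean()
        d_moved = moved.value.to_numpy() - moved.value.mean()
        np.testing.assert_allclose(d_base, d_moved, atol=1e-6)

    def test_duplicate_key_rejected(self):
        rec = pd.DataFrame(
            {
                "line": ["A", "A"],
                "environment": ["E1", "E1"],
                "replicate": [1, 1],
                "block": [1, 1],
                "trait": ["FF", "FF"],
                "value": [1.0, 2.0],
            }
        )
        with pytest.raises(ValueError, match="duplicate"):
            mg.adjust_phenotypes(rec)


class TestGeKernels:
    def test_single_environment_block_equals_main(self, small_grm):
        lines = small_grm.line_ids[:10]
        kernels = mg.build_ge_kernels(small_grm, lines, ["E1"] * 10)
        assert len(kernels) == 2
        np.testing.assert_allclose(kernels[0].K, kernels[1].K, atol=1e-12)

    def test_eigendecomposition_reconstructs_kernel(self, small_grm):
        lines = small_grm.line_ids[:8] * 2
        envs = ["E1"] * 8 + ["E2"] * 8
        for ker in mg.build_ge_kernels(small_grm, lines, envs):
            recon = ker.U @ np.diag(ker.s) @ ker.U.T
            np.testing.assert_allclose(recon, ker.K, atol=1e-8)
            assert ker.s.min() >= 0

    def test_env_blocks_tile_the_main_diagonal(self, small_grm):
        lines = small_grm.line_ids[:8] * 2
        envs = ["E1"] * 8 + ["E2"] * 8
        kernels = mg.build_ge_kernels(small_grm, lines, envs)
        total = sum(k.K for k in kernels[1:])
        np.testing.assert_allclose(np.diag(total), np.diag(kernels[0].K), atol=1e-10)

    def test_record_order_permutation(self, small_grm):
        lines = small_grm.line_ids[:6] * 2
        envs = ["E1"] * 6 + ["E2"] * 6
        kernels = mg.build_ge_kernels(small_grm, lines, envs)
        perm = np.random.default_rng(0).permutation(12)
        kp = mg.build_ge_kernels(
            small_grm, [lines[i] for i in perm], [envs[i] for i in perm]
        )
        np.testing.assert_allclose(kp[0].K, kernels[0].K[np.ix_(perm, perm)], atol=1e-12)

    def test_single_record_environment_raises(self, small_grm):
        with pytest.raises(ValueError, match="single record"):
            mg.build_ge_kernels(small_grm, small_grm.line_ids[:3], ["E1", "E1", "E2"])


class TestBGGE:
    def test_identity_kernel_fixed_variance_matches_ridge(self):
        rng = np.random.default_rng(2)
        n = 40
        y = rng.standard_normal(n) * 2 + 5
        from maizegp.bayes import EigenKernel

        ker = EigenKernel(K=np.eye(n), U=np.eye(n), s=np.ones(n), label="main-genotype")
        s2u, s2e = 1.5, 1.0
        samples = mg.fit_bgge(
            y,
            [ker],
            settings=mg.MCMCSettings(6000, 1000, 2, seed=4),
            fix_variance=(s2u, s2e),
        )
        fitted = bgge_predictions(samples)
        lam = s2e / s2u
        expect = y.mean() + (y - y.mean()) / (1 + lam)
        assert np.abs(fitted - expect).max() <= 0.05 * y.std()

    def test_zero_eigenvalue_directions_carry_no_effect(self):
        from maizegp.bayes import EigenKernel

        rng = np.random.default_rng(3)
        n = 20
        U = np.linalg.qr(rng.standard_normal((n, n)))[0]
        s = np.concatenate([np.ones(5), np.zeros(n - 5)])
        ker = EigenKernel(K=U @ np.diag(s) @ U.T, U=U, s=s, label="main-genotype")
        y = rng.standard_normal(n)
        samples = mg.fit_bgge(y, [ker], settings=mg.MCMCSettings(400, 100, 1, seed=5))
        fitted = bgge_predictions(samples) - samples.draws["fitted_mean"][0].mean()
        # fitted deviations live in the span of the nonzero eigenvectors
        proj = U[:, 5:].T @ (bgge_predictions(samples) - np.mean(bgge_predictions(samples)))
        assert np.abs(proj).max() < 0.3  # fixed-effect mean only; no effect mass outside span

    def test_agreement_with_mcmc_single_environment(self, small_phenotypes, small_grm):
        records, _ = small_phenotypes
        rec = records[(records.trait == "FF") & (records.environment == "E1")]
        rec = rec.sort_values("line").reset_index(drop=True)
        kernels = mg.build_ge_kernels(small_grm, rec["line"].tolist(), ["E1"] * len(rec))
        bg = mg.fit_bgge(
            rec["value"].to_numpy(),
            kernels,
            settings=mg.MCMCSettings(5000, 1000, 2, seed=6),
            env_labels=["E1"] * len(rec),
        )
        mc = mg.fit_mcmc_mixed(
            records, small_grm, ["FF"], mg.MCMCSettings(5000, 1000, 2, seed=7), environment="E1"
        )
        r = np.corrcoef(bgge_predictions(bg), mc.mean("u")[:, 0])[0, 1]
        assert r >= 0.95


class TestBMTME:
    def test_reduction_to_single_trait_environment(self, small_phenotypes, small_grm):
        records, _ = small_phenotypes
        rec = records[(records.trait == "FF") & (records.environment == "E1")]
        bm = fit_bmtme(rec, small_grm, mg.MCMCSettings(4000, 1000, 2, seed=8), traits=["FF"])
        mc = mg.fit_mcmc_mixed(
            records, small_grm, ["FF"], mg.MCMCSettings(4000, 1000, 2, seed=9), environment="E1"
        )
        pred = bmtme_predictions(bm).sort_values("line")["predicted"].to_numpy()
        u = mc.mean("u")[:, 0]
        assert np.corrcoef(pred, u)[0, 1] >= 0.95

    def test_trait_covariance_sign_recovery(self, small_panel, small_grm):
        cfg = mg.TraitConfig(
            genetic_correlation=0.8, replicate_sd=0.0, block_sd=0.0,
            trait_names=("FF", "MF"), asi_is_difference=False,
        )
        rec, _ = mg.simulate_phenotypes(small_panel, cfg, ("E1", "E2"), seed=10, n_replicates=1)
        bm = fit_bmtme(rec, small_grm, mg.MCMCSettings(3000, 800, 2, seed=11))
        mean_rg, _ = mg.genetic_correlation(bm, "FF", "MF")
        assert mean_rg >= 0.4

    def test_incomplete_layout_without_na_mode_raises(self, small_phenotypes, small_grm):
        records, _ = small_phenotypes
        rec = records[records.trait == "FF"].iloc[:-3]
        with pytest.raises(ValueError, match="incomplete layout"):
            fit_bmtme(rec, small_grm, mg.MCMCSettings.tiny(), traits=["FF"])

    def test_draw_count_matches_settings(self, small_phenotypes, small_grm):
        records, _ = small_phenotypes
        rec = records[records.trait == "FF"]
        settings = mg.MCMCSettings(800, 200, 3, seed=12)
        bm = fit_bmtme(rec, small_grm, settings, traits=["FF"])
        assert bm.draws["Sigma_t"].shape[0] == settings.n_draws == (800 - 200) // 3


def test_label_permutation_leaves_oracle_predictions_unchanged(small_grm):
    rng = np.random.default_rng(13)
    n = 30
    K = small_grm.values[:n, :n]
    y = rng.standard_normal(n)
    _, u = mg.blup_oracle(y, K, (np.array([[1.0]]), np.array([[1.0]])))
    perm = rng.permutation(n)
    _, up = mg.blup_oracle(y[perm], K[np.ix_(perm, perm)], (np.array([[1.0]]), np.array([[1.0]])))
    np.testing.assert_allclose(up[:, 0], u[perm, 0], atol=1e-8)
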