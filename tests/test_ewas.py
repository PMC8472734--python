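"""Binomial-GLM fits vs independent oracles, q-values, DMC calling."""

import numpy as np
import pandas as pd
import pytest
from scipy.optimize import minimize
from scipy.special import expit

from bsewas.ewas import (
    call_dmcs,
    compute_celltype_pc1,
    fit_site_model,
    run_ewas,
)
from bsewas.qvalues import compute_qvalues, estimate_pi0
from bsewas.types import ValidationError


def negloglik(beta, X, m, n):
    p = np.clip(expit(X @ beta), 1e-12, 1 - 1e-12)
    return -(m @ np.log(p) + (n - m) @ np.log(1 - p))


def oracle_mle(X, m, n):
    """Direct numerical likelihood maximization, independent of IRLS."""
    best = None
    for start in (np.zeros(X.shape[1]), np.full(X.shape[1], 0.1)):
        res = minimize(negloglik, start, args=(X, m, n), method="BFGS",
                       options={"maxiter": 2000, "gtol": 1e-10})
        if best is None or res.fun < best.fun:
            best = res
    return best.x


class TestCelltypePc1:
    def test_rank_one_pattern_explains_everything(self):
        props = np.array([[0.3, 0.7], [0.7, 0.3], [0.5, 0.5], [0.2, 0.8]])
        _, var = compute_celltype_pc1(props)
        assert var == pytest.approx(1.0)

    def test_identical_rows_rejected(self):
        with pytest.raises(ValidationError, match="constant"):
            compute_celltype_pc1(np.tile([0.1, 0.2, 0.6, 0.07, 0.03], (5, 1)))

    def test_matches_eigendecomposition_oracle(self, rng):
        props = rng.dirichlet([8, 29, 60, 2, 1], size=10)
        scores, var = compute_celltype_pc1(props)
        centered = props - props.mean(axis=0)
        evals, evecs = np.linalg.eigh(centered.T @ centered)
        v1 = evecs[:, -1]
        expected = centered @ v1
        sign = np.sign(expected @ scores)
        np.testing.assert_allclose(scores, sign * expected, atol=1e-8)
        assert var == pytest.approx(evals[-1] / evals.sum(), abs=1e-10)

    def test_neutrophil_loading_sign_fixed(self, rng):
        props = rng.dirichlet([8, 29, 60, 2, 1], size=20)
        scores, _ = compute_celltype_pc1(props)
        # higher neutrophil proportion should push pc1 up
        assert np.corrcoef(scores, props[:, 2])[0, 1] > 0


class TestFitSiteModel:
    def test_intercept_only_recovers_pooled_proportion(self):
        m = np.array([3, 7])
        n = np.array([10, 10])
        X = np.ones((2, 1))
        fit = fit_site_model(m, n, X)
        assert expit(fit["beta"][0]) == pytest.approx(0.5, abs=1e-8)

    def test_identical_groups_give_null_phenotype_effect(self):
        m = np.array([3, 5, 3, 5])
        n = np.array([10, 10, 10, 10])
        X = np.column_stack([np.ones(4), [0, 0, 1, 1]])
        fit = fit_site_model(m, n, X)
        assert abs(fit["beta"][1]) < 1e-8
        assert fit["wald_p"] == pytest.approx(1.0, abs=1e-6)

    def test_matches_likelihood_oracle_small_instances(self, rng):
        for _ in range(50):
            n_samples = int(rng.integers(6, 13))
            n_cov = int(rng.integers(1, 5))
            X = np.column_stack(
                [np.ones(n_samples), rng.integers(0, 2, size=(n_samples, n_cov))]
            )
            if np.linalg.matrix_rank(X) < X.shape[1]:
                continue
            n = rng.integers(10, 40, size=n_samples)
            p = expit(rng.normal(0, 0.8, size=n_samples))
            m = rng.binomial(n, p)
            if m.sum() == 0 or m.sum() == n.sum():
                continue
            fit = fit_site_model(m, n, X)
            if not fit["converged"] or np.abs(fit["beta"]).max() > 10:
                continue  # (near-)separated: the MLE is unbounded
            expected = oracle_mle(X, m.astype(float), n.astype(float))
            np.testing.assert_allclose(fit["beta"], expected, atol=1e-5)

    def test_n_zero_samples_excluded(self):
        m = np.array([3, 0, 7])
        n = np.array([10, 0, 10])
        X = np.ones((3, 1))
        fit = fit_site_model(m, n, X)
        assert fit["n_obs"] == 2
        assert expit(fit["beta"][0]) == pytest.approx(0.5, abs=1e-8)

    def test_rank_deficient_design_flagged_not_estimable(self):
        X = np.column_stack([np.ones(4), [1, 1, 1, 1]])
        fit = fit_site_model(np.array([1, 2, 3, 4]), np.full(4, 10), X)
        assert not fit["estimable"]


class TestRunEwas:
    def test_planted_sites_rank_high(self, small_cohort):
        mat, _, cov, truth = small_cohort
        res = run_ewas(mat, cov, phenotype="acpa")
        planted = (truth["true_beta1"] != 0).to_numpy()
        decile = np.nanquantile(res["wald_p"], 0.1)
        frac_top = (res.loc[planted, "wald_p"] <= decile).mean()
        assert frac_top >= 0.9

    def test_direction_follows_planted_sign(self, small_cohort):
        mat, _, cov, truth = small_cohort
        res = run_ewas(mat, cov, phenotype="acpa")
        hyper_truth = (truth["true_beta1"] > 0).to_numpy()
        called = res["dmc"].to_numpy() & hyper_truth
        if called.any():
            assert (res.loc[called, "direction"] == "hyper").all()

    def test_sample_order_permutation_invariance(self, small_cohort):
        mat, _, cov, _ = small_cohort
        res1 = run_ewas(mat, cov, phenotype="acpa")
        rng = np.random.default_rng(0)
        perm = rng.permutation(mat.n_samples)
        from bsewas.types import MethylationMatrix

        mat_p = MethylationMatrix(
            chrom=mat.chrom, pos=mat.pos,
            samples=[mat.samples[i] for i in perm],
            M=mat.M[:, perm], N=mat.N[:, perm],
        )
        res2 = run_ewas(mat_p, cov, phenotype="acpa")
        np.testing.assert_allclose(res1["beta1"], res2["beta1"], atol=1e-10)

    def test_constant_phenotype_rejected(self, small_cohort):
        mat, _, cov, _ = small_cohort
        cov = cov.copy()
        cov["acpa"] = "positive"
        with pytest.raises(ValidationError):
            run_ewas(mat, cov, phenotype="acpa")


class TestQvalues:
    def test_bh_hand_computation(self):
        p = np.array([0.01, 0.02, 0.03, 0.04])
        np.testing.assert_allclose(compute_qvalues(p, "bh"), [0.04] * 4)

    def test_all_ones(self):
        np.testing.assert_allclose(compute_qvalues(np.ones(5), "bh"), 1.0)
        np.testing.assert_allclose(compute_qvalues(np.ones(5), "storey"), 1.0)

    def test_storey_pi0_near_one_under_null(self, rng):
        p = rng.uniform(size=10_000)
        assert 0.9 <= estimate_pi0(p) <= 1.0

    def test_monotone_in_p(self, rng):
        p = rng.uniform(size=500)
        for method in ("bh", "storey"):
            q = compute_qvalues(p, method)
            order = np.argsort(p)
            assert (np.diff(q[order]) >= -1e-12).all()
            assert (q >= 0).all() and (q <= 1).all()

    def test_bh_at_least_storey_when_pi0_below_one(self, rng):
        p = np.concatenate([rng.uniform(size=900), rng.uniform(0, 1e-4, size=100)])
        q_bh = compute_qvalues(p, "bh")
        q_st = compute_qvalues(p, "storey")
        assert (q_bh >= q_st - 1e-12).all()

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            compute_qvalues(np.array([]))


class TestCallDmcs:
    def frame(self, q, beta1):
        return pd.DataFrame(
            {"chrom": ["chr1"] * len(q), "pos": np.arange(1, len(q) + 1),
             "beta1": beta1, "wald_p": q, "converged": True, "estimable": True}
        )

    def test_threshold_is_strict(self):
        # one site, p such that q == 0.01 exactly
        res = call_dmcs(self.frame([0.01], [1.0]), q_threshold=0.01, q_method="bh")
        assert not res["dmc"].iloc[0]

    def test_hypomethylated_direction(self):
        # BH with m=2: q(0.0099) = 2 * 0.0099 / 1 = 0.0198
        res = call_dmcs(self.frame([0.0099, 0.9], [-0.3, 0.5]),
                        q_threshold=0.02, q_method="bh")
        assert res["dmc"].iloc[0] and res["direction"].iloc[0] == "hypo"

    def test_empty_dmc_set_valid(self):
        res = call_dmcs(self.frame([0.5, 0.9], [1.0, -1.0]), q_method="bh")
        assert res["dmc"].sum() == 0
        assert (res["direction"] == "none").all()


def test_beta_binomial_null_inflates_pvalues():
    """Over-dispersed counts make the binomial Wald test anti-conservative —
    the phenomenon motivating genetic adjustment."""
    from bsewas.simulate import SimulationConfig, simulate_cohort
    from tests.conftest import attach_pc1

    base = dict(n_samples=60, n_clusters_per_chrom=25, n_dmrs=0, seed=77)
    res = {}
    for rho in (0.0, 0.15):
        mat, _, cov, _ = simulate_cohort(SimulationConfig(rho=rho, **base))
        res[rho] = run_ewas(mat, attach_pc1(cov), phenotype="acpa")
    frac_null = (res[0.0]["wald_p"] < 0.05).mean()
    frac_over = (res[0.15]["wald_p"] < 0.05).mean()
    assert frac_over > frac_null + 0.05
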