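"""Penalized-fit oracle checks, adaptive-lasso selection, gDMC calling."""

import numpy as np
import pandas as pd
import pytest
from scipy.optimize import minimize
from scipy.special import expit

from bsewas.adjust import call_gdmcs, refit_adjusted, adaptive_lasso_select
from bsewas.ewas import fit_site_model
from bsewas.penalized import (
    fit_penalized_binomial,
    lambda_path,
    one_se_lambda,
    penalized_objective,
    stratified_folds,
    cv_penalized_binomial,
)
from bsewas.qvalues import p_threshold_for_q


def oracle_penalized(X, m, n, pf, lam):
    """Exact L1 oracle: split beta = a - b with a, b >= 0, smooth objective,
    box-constrained quasi-Newton — independent of coordinate descent."""
    p = X.shape[1]

    # the |beta| term becomes a+b (exact when a*b = 0 at the optimum)
    def obj_exact(ab):
        a, b = ab[:p], ab[p:]
        beta = a - b
        pr = np.clip(expit(X @ beta), 1e-8, 1 - 1e-8)
        ll = m @ np.log(pr) + (n - m) @ np.log(1 - pr)
        return -ll / n.sum() + lam * float(pf @ (a + b))

    best = None
    for s in (0.0, 0.05):
        res = minimize(obj_exact, np.full(2 * p, s), method="L-BFGS-B",
                       bounds=[(0, None)] * 2 * p,
                       options={"maxiter": 5000, "ftol": 1e-14, "gtol": 1e-10})
        if best is None or res.fun < best.fun:
            best = res
    return best.x[:p] - best.x[p:]


def random_instance(rng, n=25, n_snps=3, effect=1.0):
    X = np.column_stack([np.ones(n), rng.integers(0, 2, size=n)])
    S = rng.binomial(2, 0.3, size=(n, n_snps)).astype(float)
    S = (S - S.mean(0)) / np.maximum(S.std(0), 1e-9)
    depth = rng.integers(10, 40, size=n)
    eta = -0.5 + 0.8 * X[:, 1] + effect * S[:, 0]
    mcounts = rng.binomial(depth, expit(eta))
    full = np.column_stack([X, S])
    pf = np.concatenate([np.zeros(2), np.ones(n_snps)])
    return full, mcounts.astype(float), depth.astype(float), pf


class TestPenalizedOracle:
    def test_matches_exact_l1_oracle_at_fixed_lambda(self, rng):
        for trial in range(8):
            full, m, n, pf = random_instance(rng)
            for lam in (0.002, 0.01, 0.05):
                beta_cd = fit_penalized_binomial(full, m, n, pf, lam)
                beta_or = oracle_penalized(full, m, n, pf, lam)
                obj_cd = penalized_objective(beta_cd, full, m, n, pf, lam)
                obj_or = penalized_objective(beta_or, full, m, n, pf, lam)
                assert obj_cd <= obj_or + 1e-6
                np.testing.assert_allclose(beta_cd, beta_or, atol=1e-3)

    def test_unpenalized_limit_matches_glm(self, rng):
        full, m, n, pf = random_instance(rng)
        beta = fit_penalized_binomial(full, m, n, np.zeros_like(pf), 0.0)
        glm = fit_site_model(m, n, full)
        np.testing.assert_allclose(beta, glm["beta"], atol=1e-5)

    def test_lambda_max_zeroes_all_penalized_terms(self, rng):
        full, m, n, pf = random_instance(rng)
        lams = lambda_path(full, m, n, pf)
        beta = fit_penalized_binomial(full, m, n, pf, lams[0])
        assert np.abs(beta[2:]).max() < 1e-8


def test_one_se_selection_is_subset_of_min_selection(rng):
    """The 1-SE rule picks a larger penalty, so its active set should nest
    inside the CV-minimum active set for the vast majority of sites."""
    nested = 0
    total = 0
    for trial in range(20):
        full, m, n, pf = random_instance(rng, n=60, n_snps=5)
        lams = lambda_path(full, m, n, pf)
        folds = stratified_folds(full[:, 1], 5, rng)
        cv_mean, cv_se = cv_penalized_binomial(full, m, n, pf, lams, folds)
        lam_1se, lam_min = one_se_lambda(lams, cv_mean, cv_se)
        b1 = fit_penalized_binomial(full, m, n, pf, lam_1se)
        b2 = fit_penalized_binomial(full, m, n, pf, lam_min)
        set1 = set(np.where(np.abs(b1[2:]) > 1e-10)[0])
        set2 = set(np.where(np.abs(b2[2:]) > 1e-10)[0])
        total += 1
        if set1 <= set2:
            nested += 1
    assert nested / total >= 0.95


class TestAdaptiveLassoSelection:
    def design(self, cov):
        from bsewas.ewas import build_design

        return build_design(cov).to_numpy()

    def simulate_site(self, rng, n=100, causal_effect=0.0, n_noise=20):
        """One CpG with optional causal SNP among noise SNPs."""
        pheno = (np.arange(n) < n // 2).astype(float)
        X = np.column_stack([np.ones(n), pheno, rng.normal(54, 8, n),
                             rng.integers(0, 2, n), rng.integers(0, 2, n),
                             rng.normal(0, 0.05, n)])
        S = rng.binomial(2, rng.uniform(0.1, 0.5, size=n_noise + 1),
                         size=(n, n_noise + 1)).astype(float)
        depth = rng.integers(20, 45, size=n)
        eta = -causal_effect * S[:, 0].mean() + causal_effect * S[:, 0]
        m = rng.binomial(depth, expit(eta + 0.2 * pheno - 0.1))
        ids = [f"snp{j}" for j in range(n_noise + 1)]
        return m.astype(float), depth.astype(float), X, S, ids

    def test_null_selection_mostly_empty(self, rng):
        empty = 0
        for rep in range(10):
            m, n, X, S, ids = self.simulate_site(rng, causal_effect=0.0)
            sel = adaptive_lasso_select(m, n, X, S, ids, seed=rep)
            empty += int(len(sel) == 0)
        assert empty >= 8

    def test_causal_snp_selected(self, rng):
        hits = 0
        for rep in range(10):
            m, n, X, S, ids = self.simulate_site(rng, causal_effect=1.0)
            sel = adaptive_lasso_select(m, n, X, S, ids, seed=rep)
            hits += int("snp0" in sel)
        assert hits >= 9

    def test_duplicated_causal_column_selects_at_most_one(self, rng):
        m, n, X, S, ids = self.simulate_site(rng, causal_effect=1.2, n_noise=3)
        S[:, 1] = S[:, 0]  # exact duplicate of the causal column
        sel = adaptive_lasso_select(m, n, X, S, ids, seed=0)
        assert len({"snp0", "snp1"} & set(sel)) <= 1


class TestRefit:
    def test_empty_selection_returns_unadjusted(self, rng):
        m, n_, X, S, _ = TestAdaptiveLassoSelection().simulate_site(rng)
        unadj = fit_site_model(m, n_, X)
        out = refit_adjusted(m, n_, X, None, unadjusted=unadj)
        assert out is unadj

    def test_confounded_site_attenuates(self, rng):
        """When the SNP drives both methylation and phenotype, adjusting for
        it should weaken the phenotype association."""
        worse = 0
        for rep in range(10):
            n = 150
            rng2 = np.random.default_rng(1000 + rep)
            dose = rng2.binomial(2, 0.4, size=n).astype(float)
            pheno = rng2.binomial(1, expit(1.5 * (dose - dose.mean()))).astype(float)
            X = np.column_stack([np.ones(n), pheno])
            depth = rng2.integers(20, 45, size=n)
            m = rng2.binomial(depth, expit(1.2 * (dose - dose.mean())))
            unadj = fit_site_model(m, depth, X)
            adj = refit_adjusted(m, depth, X, dose[:, None], unadjusted=unadj)
            if adj["wald_p"] > unadj["wald_p"]:
                worse += 1
        assert worse >= 9

    def test_aic_improves_with_truly_causal_snp(self, rng):
        m, n_, X, S, _ = TestAdaptiveLassoSelection().simulate_site(
            rng, causal_effect=1.2
        )
        unadj = fit_site_model(m, n_, X)
        adj = refit_adjusted(m, n_, X, S[:, :1], unadjusted=unadj)
        assert adj["aic"] < unadj["aic"]

    def test_collinear_selection_dropped(self, rng):
        m, n_, X, S, _ = TestAdaptiveLassoSelection().simulate_site(
            rng, causal_effect=1.0, n_noise=2
        )
        S_dup = np.column_stack([S[:, 0], S[:, 0]])
        adj = refit_adjusted(m, n_, X, S_dup)
        assert adj["estimable"]
        assert len(adj["beta"]) == X.shape[1] + 1


class TestGdmcCalling:
    def frame(self, p_values, converged=True):
        return pd.DataFrame(
            {
                "chrom": ["chr1"] * len(p_values),
                "pos": np.arange(1, len(p_values) + 1),
                "beta1_adjusted": [0.5] * len(p_values),
                "p_adjusted": p_values,
                "converged": converged,
            }
        )

    def test_threshold_strict_at_3e5(self):
        out = call_gdmcs(self.frame([3e-5]))
        assert not out["gdmc"].iloc[0]

    def test_below_threshold_called(self):
        out = call_gdmcs(self.frame([1e-6]))
        assert out["gdmc"].iloc[0] and out["direction"].iloc[0] == "hyper"

    def test_empty_input_gives_empty_output(self):
        out = call_gdmcs(self.frame([]))
        assert len(out) == 0

    def test_non_converged_excluded(self):
        out = call_gdmcs(self.frame([1e-9], converged=False))
        assert not out["gdmc"].iloc[0]


class TestPThresholdForQ:
    def test_hand_bh_computation(self):
        p = np.array([1e-6, 1e-4, 0.5, 0.9])
        # BH: q(1e-4) = 4 * 1e-4 / 2 = 2e-4 < 0.01 -> threshold 1e-4
        assert p_threshold_for_q(p, 0.01, method="bh") == pytest.approx(1e-4)

    def test_nothing_significant_gives_zero(self):
        assert p_threshold_for_q(np.full(4, 0.5), 0.01, method="bh") == 0.0

    def test_non_decreasing_when_small_ps_added(self, rng):
        p = rng.uniform(size=200)
        t1 = p_threshold_for_q(p, 0.01, method="bh")
        t2 = p_threshold_for_q(np.concatenate([p, np.full(50, 1e-8)]), 0.01,
                               method="bh")
        assert t2 >= t1

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            p_threshold_for_q(np.array([]))
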