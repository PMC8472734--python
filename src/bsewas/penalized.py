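"""L1-penalized grouped-binomial regression with per-coefficient penalties.

This is the engine behind adaptive-lasso selection of cis-meQTLs: a
glmnet-style coordinate-descent solver for

    obj(beta) = -(1/W) * sum_i [ m_i log p_i + (n_i - m_i) log(1 - p_i) ]
                + lambda * sum_j pf_j * |beta_j|,

with logit(p_i) = x_i' beta, W = sum_i n_i, and penalty factors pf_j >= 0
(pf_j = 0 leaves a coefficient unpenalized — the intercept, the phenotype
and the environmental covariates; adaptive weights 1/|beta_tilde_j| go on
the genetic terms).  The outer loop is IRLS on the working response; the
inner loop is cyclic coordinate descent with soft-thresholding.  Lambda
paths use warm starts, and k-fold cross-validation scores held-out
binomial deviance per unit read weight.
"""

from __future__ import annotations

import numba
import numpy as np

EPS_P = 1e-8


@numba.njit(cache=False)
def _cd_sweep(X, w, beta, r, wx2, pf, lam, max_inner, tol):
    """Cyclic coordinate descent on the weighted least-squares surrogate.

    Mutates ``beta`` and the partial residual ``r`` in place; returns the
    number of full sweeps used.
    """
    n, p = X.shape
    for it in range(max_inner):
        max_delta = 0.0
        for j in range(p):
            if wx2[j] <= 0.0:
                continue
            bj_old = beta[j]
            rho = wx2[j] * bj_old
            for i in range(n):
                rho += w[i] * X[i, j] * r[i]
            gamma = lam * pf[j]
            if rho > gamma:
                bj = (rho - gamma) / wx2[j]
            elif rho < -gamma:
                bj = (rho + gamma) / wx2[j]
            else:
                bj = 0.0
            if bj != bj_old:
                delta = bj - bj_old
                for i in range(n):
                    r[i] -= X[i, j] * delta
                beta[j] = bj
                if abs(delta) > max_delta:
                    max_delta = abs(delta)
        if max_delta < tol:
            return it + 1
    return max_inner


def _sigmoid(eta: np.ndarray) -> np.ndarray:
    with np.errstate(over="ignore"):
        return 1.0 / (1.0 + np.exp(-eta))


def binomial_deviance(beta: np.ndarray, X: np.ndarray, m: np.ndarray,
                      n: np.ndarray) -> float:
    """-2 * log-likelihood per unit total read weight (saturated part omitted)."""
    p = np.clip(_sigmoid(X @ beta), EPS_P, 1 - EPS_P)
    ll = m @ np.log(p) + (n - m) @ np.log(1 - p)
    return float(-2.0 * ll / n.sum())


def penalized_objective(beta: np.ndarray, X: np.ndarray, m: np.ndarray,
                        n: np.ndarray, penalty_factors: np.ndarray,
                        lam: float) -> float:
    p = np.clip(_sigmoid(X @ beta), EPS_P, 1 - EPS_P)
    ll = m @ np.log(p) + (n - m) @ np.log(1 - p)
    return float(-ll / n.sum() + lam * np.abs(beta) @ penalty_factors)


def _soft_threshold(z: float, gamma: float) -> float:
    if z > gamma:
        return z - gamma
    if z < -gamma:
        return z + gamma
    return 0.0


def fit_penalized_binomial(
    X: np.ndarray,
    m: np.ndarray,
    n: np.ndarray,
    penalty_factors: np.ndarray,
    lam: float,
    beta_init: np.ndarray | None = None,
    max_outer: int = 100,
    max_inner: int = 1000,
    tol: float = 1e-8,
) -> np.ndarray:
    """Minimize the penalized objective at a single lambda."""
    X = np.asarray(X, dtype=float)
    m = np.asarray(m, dtype=float)
    n = np.asarray(n, dtype=float)
    pf = np.asarray(penalty_factors, dtype=float)
    n_obs, n_coef = X.shape
    W = n.sum()
    beta = np.zeros(n_coef) if beta_init is None else beta_init.copy()
    for _ in range(max_outer):
        eta = X @ beta
        p = np.clip(_sigmoid(eta), EPS_P, 1 - EPS_P)
        w = n * p * (1 - p) / W  # IRLS weights, normalized by total trials
        z = eta + (m - n * p) / np.maximum(n * p * (1 - p), 1e-12)
        beta_old_outer = beta.copy()
        wx2 = w @ (X**2)
        r = z - X @ beta
        _cd_sweep(np.ascontiguousarray(X), w, beta, r, wx2, pf, lam,
                  max_inner, tol)
        if np.max(np.abs(beta - beta_old_outer)) < tol * (1 + np.max(np.abs(beta))):
            break
    return beta


def lambda_path(
    X: np.ndarray,
    m: np.ndarray,
    n: np.ndarray,
    penalty_factors: np.ndarray,
    n_lambda: int = 50,
    lambda_min_ratio: float = 1e-3,
) -> np.ndarray:
    """Descending lambda grid from the smallest lambda that zeroes every
    penalized coefficient (given the unpenalized terms fitted alone)."""
    pf = np.asarray(penalty_factors, dtype=float)
    free = pf == 0
    beta0 = np.zeros(X.shape[1])
    if free.any():
        beta0[free] = fit_penalized_binomial(
            X[:, free], m, n, np.zeros(free.sum()), lam=0.0
        )
    p = np.clip(_sigmoid(X @ beta0), EPS_P, 1 - EPS_P)
    grad = X.T @ (m - n * p) / n.sum()
    with np.errstate(divide="ignore"):
        lam_max = float(np.max(np.abs(grad[~free]) / pf[~free]))
    lam_max = max(lam_max, 1e-10)
    return np.geomspace(lam_max, lam_max * lambda_min_ratio, n_lambda)


def fit_path(
    X: np.ndarray,
    m: np.ndarray,
    n: np.ndarray,
    penalty_factors: np.ndarray,
    lambdas: np.ndarray,
) -> np.ndarray:
    """Warm-started coefficient matrix, one row per lambda (descending)."""
    betas = np.zeros((len(lambdas), X.shape[1]))
    beta = None
    for i, lam in enumerate(lambdas):
        beta = fit_penalized_binomial(X, m, n, penalty_factors, lam, beta_init=beta)
        betas[i] = beta
    return betas


def stratified_folds(strata: np.ndarray, n_folds: int,
                     rng: np.random.Generator) -> np.ndarray:
    """Fold assignment balanced within each stratum level."""
    strata = np.asarray(strata)
    fold = np.empty(len(strata), dtype=int)
    for level in np.unique(strata):
        idx = np.where(strata == level)[0]
        perm = rng.permutation(len(idx))
        fold[idx[perm]] = np.arange(len(idx)) % n_folds
    return fold


def cv_penalized_binomial(
    X: np.ndarray,
    m: np.ndarray,
    n: np.ndarray,
    penalty_factors: np.ndarray,
    lambdas: np.ndarray,
    folds: np.ndarray,
    penalty_fn=None,
) -> tuple[np.ndarray, np.ndarray]:
    """Cross-validated held-out binomial deviance per lambda.

    Returns (mean, standard error) across folds; folds with no held-out
    reads contribute nothing.  When ``penalty_fn`` is given it is called
    with the boolean training mask and must return that fold's penalty
    factors — used to cross-validate data-dependent (adaptive) weights so
    the held-out deviance carries no information leak.
    """
    fold_ids = np.unique(folds)
    dev = np.full((len(fold_ids), len(lambdas)), np.nan)
    for fi, f in enumerate(fold_ids):
        train, test = folds != f, folds == f
        if n[test].sum() == 0 or n[train].sum() == 0:
            continue
        pf_fold = penalty_factors if penalty_fn is None else penalty_fn(train)
        betas = fit_path(X[train], m[train], n[train], pf_fold, lambdas)
        for li in range(len(lambdas)):
            dev[fi, li] = binomial_deviance(betas[li], X[test], m[test], n[test])
    mean = np.nanmean(dev, axis=0)
    k = np.sum(~np.isnan(dev), axis=0)
    se = np.nanstd(dev, axis=0, ddof=1) / np.sqrt(np.maximum(k, 1))
    return mean, se


def one_se_lambda(lambdas: np.ndarray, cv_mean: np.ndarray,
                  cv_se: np.ndarray) -> tuple[float, float]:
    """(lambda_1se, lambda_min): largest lambda within one SE of the
    minimum cross-validated deviance, and the minimizer itself."""
    i_min = int(np.nanargmin(cv_mean))
    bound = cv_mean[i_min] + cv_se[i_min]
    within = np.where(cv_mean <= bound)[0]
    i_1se = int(within[0])  # lambdas are descending: first index = largest
    return float(lambdas[i_1se]), float(lambdas[i_min])
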