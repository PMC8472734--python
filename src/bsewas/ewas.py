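"""Per-CpG weighted binomial regression EWAS.

At each CpG the methylated read count is modelled as

    M_i ~ Binomial(N_i, p_i),
    logit(p_i) = b0 + b1*phenotype_i + b2*age_i + b3*sex_i + b4*smoking_i + b5*PC1_i

where the phenotype is ACPA positivity (or self-reported RA status), and
PC1 is the first principal component of the five measured blood-cell
proportions.  "Weighted" means the grouped-binomial likelihood with N_i
trials — equivalently a proportion response weighted by read depth.  The
phenotype coefficient's Wald z-test provides the per-site p-value; FDR
q-values flag differentially methylated cytosines (DMCs), hypermethylated
when b1 > 0.

Coding conventions (fixed and logged): sex female = 1, male = 0; smoking is
current = 1 vs everything else = 0, with 'missing' mapped to 0 and warned
about (an explicit missing-indicator column is available via
``smoking_missing_indicator``).
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.stats import norm

from .qvalues import compute_qvalues
from .types import CELL_TYPES, MethylationMatrix, ValidationError

log = logging.getLogger(__name__)

DESIGN_COLUMNS = ["intercept", "phenotype", "age", "sex", "smoking", "pc1"]

MAX_ITER = 50
TOL = 1e-8


def compute_celltype_pc1(cell_props: np.ndarray) -> tuple[np.ndarray, float]:
    """First principal component of the cell-proportion matrix.

    Columns are mean-centered; scores are the projection on the first right
    singular vector, sign-fixed so that the neutrophil loading (column 2 of
    the canonical monocyte/lymphocyte/neutrophil/eosinophil/basophil order)
    is positive.  Returns (scores, fraction of variance explained).
    """
    X = np.asarray(cell_props, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValidationError("need at least two samples of cell proportions")
    if not np.isfinite(X).all():
        raise ValidationError("non-finite cell proportions")
    centered = X - X.mean(axis=0)
    if np.allclose(centered, 0.0):
        raise ValidationError("constant cell composition: PC1 undefined")
    _, s, vt = np.linalg.svd(centered, full_matrices=False)
    v1 = vt[0]
    neutrophil_col = CELL_TYPES.index("neutrophil") if X.shape[1] == 5 else int(np.argmax(np.abs(v1)))
    if v1[neutrophil_col] < 0:
        v1 = -v1
    scores = centered @ v1
    var_explained = float(s[0] ** 2 / (s**2).sum())
    return scores, var_explained


def build_nuisance(cov: pd.DataFrame) -> pd.DataFrame:
    """Intercept + the four nuisance covariates (no phenotype column)."""
    if "pc1" not in cov.columns:
        raise ValidationError("covariates lack pc1; run compute_celltype_pc1 first")
    return pd.DataFrame(
        {
            "intercept": 1.0,
            "age": cov["age"].to_numpy(dtype=float),
            "sex": (cov["sex"] == "female").to_numpy(dtype=float),
            "smoking": (cov["smoking"] == "current").to_numpy(dtype=float),
            "pc1": cov["pc1"].to_numpy(dtype=float),
        }
    )


def smoking_missing_indicator(cov: pd.DataFrame) -> np.ndarray:
    return (cov["smoking"] == "missing").to_numpy(dtype=float)


def build_design(
    cov: pd.DataFrame,
    phenotype: str = "acpa",
    include_missing_indicator: bool = False,
) -> pd.DataFrame:
    """Design matrix aligned with the covariate table's row order.

    ``phenotype`` selects the contrast: 'acpa' codes positive = 1 vs
    negative = 0; 'ra' codes yes = 1 vs no = 0.
    """
    if phenotype == "acpa":
        pheno = (cov["acpa"] == "positive").to_numpy(dtype=float)
    elif phenotype == "ra":
        pheno = (cov["ra"] == "yes").to_numpy(dtype=float)
    else:
        raise ValidationError(f"unknown phenotype {phenotype!r}")
    if pheno.min() == pheno.max():
        raise ValidationError(f"phenotype {phenotype!r} is constant in this cohort")
    if "pc1" not in cov.columns:
        raise ValidationError("covariates lack pc1; run compute_celltype_pc1 first")
    n_missing = int((cov["smoking"] == "missing").sum())
    if n_missing:
        log.warning(
            "%d samples with missing smoking status coded as non-current", n_missing
        )
    X = pd.DataFrame(
        {
            "intercept": 1.0,
            "phenotype": pheno,
            "age": cov["age"].to_numpy(dtype=float),
            "sex": (cov["sex"] == "female").to_numpy(dtype=float),
            "smoking": (cov["smoking"] == "current").to_numpy(dtype=float),
            "pc1": cov["pc1"].to_numpy(dtype=float),
        }
    )
    if include_missing_indicator:
        X["smoking_missing"] = smoking_missing_indicator(cov)
    return X


def fit_site_model(
    m: np.ndarray,
    n: np.ndarray,
    X: np.ndarray,
    max_iter: int = MAX_ITER,
    tol: float = TOL,
) -> dict:
    """IRLS fit of the grouped-binomial GLM at one site.

    Samples with n == 0 are excluded.  Returns coefficient vector, Wald SE
    and two-sided Wald p for the column-1 (phenotype) coefficient, the
    maximized log-likelihood, AIC/BIC, and convergence/estimability flags.
    """
    m = np.asarray(m, dtype=float)
    n = np.asarray(n, dtype=float)
    X = np.asarray(X, dtype=float)
    covered = n > 0
    m, n, Xc = m[covered], n[covered], X[covered]
    out = {
        "beta": np.full(X.shape[1], np.nan),
        "se1": np.nan,
        "wald_p": np.nan,
        "loglik": np.nan,
        "aic": np.nan,
        "bic": np.nan,
        "n_obs": int(covered.sum()),
        "converged": False,
        "estimable": False,
    }
    if covered.sum() == 0:
        return out
    if np.linalg.matrix_rank(Xc) < Xc.shape[1]:
        return out
    model = sm.GLM(np.column_stack([m, n - m]), Xc, family=sm.families.Binomial())
    with np.errstate(all="ignore"):
        try:
            fit = model.fit(maxiter=max_iter, tol=tol)
        except Exception:
            return out
    beta = np.asarray(fit.params, dtype=float)
    se = np.asarray(fit.bse, dtype=float)
    converged = bool(getattr(fit, "converged", True)) and np.isfinite(beta).all()
    # complete separation shows up as exploding coefficients / SEs
    if np.abs(beta).max() > 1e2 or not np.isfinite(se).all():
        converged = False
    out.update(
        beta=beta,
        se1=float(se[1]) if len(se) > 1 else np.nan,
        loglik=float(fit.llf),
        aic=float(fit.aic),
        bic=float(fit.bic_llf),
        converged=converged,
        estimable=True,
    )
    if len(beta) > 1 and converged:
        z = beta[1] / se[1]
        out["wald_p"] = float(2.0 * norm.sf(abs(z)))
    return out


def run_ewas(
    mat: MethylationMatrix,
    covariates: pd.DataFrame,
    phenotype: str = "acpa",
    q_method: str = "storey",
    q_threshold: float = 0.01,
) -> pd.DataFrame:
    """Fit the binomial GLM at every site and call DMCs at q < threshold.

    Returns one row per site: beta0..beta5, se and Wald p for the phenotype
    coefficient, q (NaN for non-estimable or non-converged sites, which are
    excluded from the FDR computation), the dmc flag and direction.
    """
    cov = covariates.set_index("sample_id").loc[mat.samples].reset_index()
    X = build_design(cov, phenotype=phenotype).to_numpy()
    rows = []
    for k in range(mat.n_sites):
        fit = fit_site_model(mat.M[k], mat.N[k], X)
        beta = fit["beta"]
        rows.append(
            {
                "chrom": mat.chrom[k],
                "pos": int(mat.pos[k]),
                **{f"beta{j}": beta[j] if j < len(beta) else np.nan for j in range(6)},
                "se1": fit["se1"],
                "wald_p": fit["wald_p"],
                "loglik": fit["loglik"],
                "aic": fit["aic"],
                "bic": fit["bic"],
                "converged": fit["converged"],
                "estimable": fit["estimable"],
            }
        )
    results = pd.DataFrame(rows)
    n_bad = int((~(results["converged"] & results["estimable"])).sum())
    if n_bad:
        log.info("%d sites non-estimable or non-converged (excluded from FDR)", n_bad)
    return call_dmcs(results, q_threshold=q_threshold, q_method=q_method)


def call_dmcs(
    results: pd.DataFrame, q_threshold: float = 0.01, q_method: str = "storey"
) -> pd.DataFrame:
    """Attach q-values and the DMC flag/direction to a site-result table.

    DMC iff q < threshold (strict); direction 'hyper' iff dmc and beta1 > 0.
    """
    results = results.copy()
    ok = results["wald_p"].notna().to_numpy()
    q = np.full(len(results), np.nan)
    if ok.any():
        q[ok] = compute_qvalues(results.loc[ok, "wald_p"].to_numpy(), method=q_method)
    results["q"] = q
    results["dmc"] = (results["q"] < q_threshold).fillna(False)
    direction = np.where(
        results["dmc"] & (results["beta1"] > 0),
        "hyper",
        np.where(results["dmc"], "hypo", "none"),
    )
    results["direction"] = direction
    return results
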