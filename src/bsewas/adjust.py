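"""Genetically adjusted EWAS: adaptive-lasso SNP selection and refits.

For every DMC with at least one cis-meQTL, the site's candidate SNP
dosages enter a penalized binomial regression in which the intercept,
phenotype and environmental covariates stay unpenalized while each genetic
term j carries an adaptive L1 weight 1/|beta_tilde_j| (beta_tilde from an
unpenalized single-SNP marginal fit; gamma = 1, weight capped at 1e6).
The penalty is chosen by five-fold phenotype-stratified cross-validation
with the one-standard-error rule.  SNPs retaining non-zero coefficients
are carried into an unpenalized refit, and the refitted phenotype Wald
p-value is compared against a fixed epigenome-wide threshold (3e-5,
roughly FDR 0.01 over the full CpG universe) to call genetically adjusted
DMCs (gDMCs).  gDMRs follow by the ordinary region-merging rule applied to
gDMCs.  DMCs with no cis-meQTL keep their unadjusted fit unchanged.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .ewas import build_design, fit_site_model
from .penalized import (
    cv_penalized_binomial,
    fit_penalized_binomial,
    lambda_path,
    one_se_lambda,
    stratified_folds,
)
from .types import GenotypeMatrix, MethylationMatrix

log = logging.getLogger(__name__)

GDMC_P_THRESHOLD = 3e-5
WEIGHT_CAP = 1e6


def marginal_snp_weights(
    m: np.ndarray, n: np.ndarray, X: np.ndarray, S: np.ndarray,
    gamma: float = 1.0, cap: float = WEIGHT_CAP,
) -> np.ndarray:
    """Adaptive penalty weights w_j = 1 / |beta_tilde_j|**gamma.

    beta_tilde_j is the SNP coefficient from an unpenalized binomial fit
    of the site on the base design plus SNP j alone; zero or failed
    marginal fits get the cap.
    """
    weights = np.empty(S.shape[1])
    for j in range(S.shape[1]):
        fit = fit_site_model(m, n, np.column_stack([X, S[:, j]]))
        bj = fit["beta"][-1] if fit["estimable"] else np.nan
        if not np.isfinite(bj) or bj == 0.0:
            weights[j] = cap
        else:
            weights[j] = min(1.0 / abs(bj) ** gamma, cap)
    return weights


def adaptive_lasso_select(
    m: np.ndarray,
    n: np.ndarray,
    X: np.ndarray,
    S: np.ndarray,
    snp_ids: list[str],
    folds: int = 5,
    seed: int = 0,
    gamma: float = 1.0,
) -> list[str]:
    """Select cis-meQTLs with non-zero coefficients at the 1-SE lambda.

    ``X`` is the unpenalized design (intercept, phenotype, covariates);
    ``S`` the candidate dosage matrix (columns standardized internally).
    Exactly collinear duplicates resolve by coordinate-descent cycle order
    (the earlier column wins).  Returns selected SNP ids (possibly empty).
    """
    covered = np.asarray(n) > 0
    m, n = np.asarray(m, float)[covered], np.asarray(n, float)[covered]
    X, S = np.asarray(X, float)[covered], np.asarray(S, float)[covered]
    sd = S.std(axis=0, ddof=0)
    usable = sd > 0
    if not usable.any():
        log.info("all candidate SNPs constant; empty selection")
        return []
    S_std = (S[:, usable] - S[:, usable].mean(axis=0)) / sd[usable]
    ids = [sid for sid, u in zip(snp_ids, usable) if u]
    n_base = X.shape[1]

    def adaptive_pf(subset: np.ndarray) -> np.ndarray:
        """Mean-1-normalized adaptive weights estimated on ``subset`` —
        recomputed per CV training fold so the held-out deviance carries
        no information from the test samples."""
        w = marginal_snp_weights(m[subset], n[subset], X[subset],
                                 S_std[subset], gamma=gamma)
        return np.concatenate([np.zeros(n_base), w / w.mean()])

    full = np.column_stack([X, S_std])
    pf = adaptive_pf(np.ones(len(m), dtype=bool))
    lambdas = lambda_path(full, m, n, pf)
    strata = X[:, 1] if X.shape[1] > 1 else np.zeros(len(m))
    fold_assign = stratified_folds(strata, folds, np.random.default_rng(seed))
    cv_mean, cv_se = cv_penalized_binomial(full, m, n, pf, lambdas, fold_assign,
                                           penalty_fn=adaptive_pf)
    lam_1se, _ = one_se_lambda(lambdas, cv_mean, cv_se)
    beta = fit_penalized_binomial(full, m, n, pf, lam_1se)
    nonzero = np.abs(beta[X.shape[1]:]) > 1e-10
    return [sid for sid, nz in zip(ids, nonzero) if nz]


def refit_adjusted(
    m: np.ndarray,
    n: np.ndarray,
    X: np.ndarray,
    S_selected: np.ndarray | None,
    unadjusted: dict | None = None,
) -> dict:
    """Unpenalized binomial refit with the selected SNP dosages appended.

    With an empty selection the unadjusted fit is returned unchanged (when
    provided) or recomputed.  Collinear SNP columns are dropped in
    selection order until the design is full rank.
    """
    if S_selected is None or S_selected.shape[1] == 0:
        return unadjusted if unadjusted is not None else fit_site_model(m, n, X)
    covered = np.asarray(n) > 0
    keep_cols: list[int] = []
    Xc = np.asarray(X, float)[covered]
    Sc = np.asarray(S_selected, float)[covered]
    for j in range(Sc.shape[1]):
        trial = np.column_stack([Xc] + [Sc[:, k:k + 1] for k in keep_cols + [j]])
        if np.linalg.matrix_rank(trial) == trial.shape[1]:
            keep_cols.append(j)
        else:
            log.info("dropping collinear SNP column %d from refit", j)
    design = np.column_stack([X, S_selected[:, keep_cols]])
    return fit_site_model(m, n, design)


def adjust_dmcs(
    mat: MethylationMatrix,
    dmc_results: pd.DataFrame,
    meqtl_table: pd.DataFrame,
    geno: GenotypeMatrix,
    covariates: pd.DataFrame,
    phenotype: str = "acpa",
    folds: int = 5,
    seed: int = 0,
    p_threshold: float = GDMC_P_THRESHOLD,
) -> pd.DataFrame:
    """Run selection + refit over every DMC; call gDMCs at p < threshold.

    ``meqtl_table`` must carry site_idx/snp_idx columns (from scan_meqtl)
    and an ``is_meqtl`` flag; candidates for a DMC are its q-significant
    cis-meQTLs.  Returns one row per DMC with the adjusted phenotype
    coefficient, p, AIC/BIC before and after, selected SNP ids and flags.
    """
    cov = covariates.set_index("sample_id").loc[mat.samples].reset_index()
    X = build_design(cov, phenotype=phenotype).to_numpy()
    sig = meqtl_table[meqtl_table["is_meqtl"]]
    by_site: dict[int, pd.DataFrame] = dict(tuple(sig.groupby("site_idx")))
    site_lookup = {
        (c, int(p)): i for i, (c, p) in enumerate(zip(mat.chrom, mat.pos))
    }
    rows = []
    dmcs = dmc_results[dmc_results["dmc"]]
    for _, site in dmcs.iterrows():
        key = (site["chrom"], int(site["pos"]))
        site_idx = site_lookup[key]
        m, n = mat.M[site_idx], mat.N[site_idx]
        unadj = fit_site_model(m, n, X)
        cands = by_site.get(site_idx)
        if cands is None or len(cands) == 0:
            selected: list[str] = []
            refit = unadj
        else:
            snp_idx = cands["snp_idx"].to_numpy()
            snp_ids = cands["snp_id"].tolist()
            S = geno.dosage[snp_idx].T
            selected = adaptive_lasso_select(
                m, n, X, S, snp_ids, folds=folds, seed=seed + site_idx
            )
            sel_pos = [snp_ids.index(s) for s in selected]
            refit = refit_adjusted(m, n, X, S[:, sel_pos] if sel_pos else None,
                                   unadjusted=unadj)
        rows.append(
            {
                "chrom": site["chrom"],
                "pos": int(site["pos"]),
                "beta1_unadjusted": site["beta1"],
                "beta1_adjusted": refit["beta"][1],
                "p_unadjusted": site["wald_p"],
                "p_adjusted": refit["wald_p"],
                "n_candidates": 0 if cands is None else len(cands),
                "selected_snps": ",".join(selected),
                "n_selected": len(selected),
                "aic_before": unadj["aic"],
                "aic_after": refit["aic"],
                "bic_before": unadj["bic"],
                "bic_after": refit["bic"],
                "converged": refit["converged"],
            }
        )
    adjusted = pd.DataFrame(
        rows,
        columns=["chrom", "pos", "beta1_unadjusted", "beta1_adjusted",
                 "p_unadjusted", "p_adjusted", "n_candidates", "selected_snps",
                 "n_selected", "aic_before", "aic_after", "bic_before",
                 "bic_after", "converged"],
    )
    return call_gdmcs(adjusted, p_threshold=p_threshold)


def call_gdmcs(adjusted: pd.DataFrame, p_threshold: float = GDMC_P_THRESHOLD
               ) -> pd.DataFrame:
    """gDMC iff the adjusted phenotype p-value is strictly below threshold.

    Non-converged refits are excluded from gDMC calling (kept in the table
    with gdmc = False).  The direction column reflects the adjusted
    coefficient sign so gDMRs can be built by the ordinary region caller.
    """
    out = adjusted.copy()
    p = out["p_adjusted"]
    out["gdmc"] = (p < p_threshold) & out["converged"] & p.notna()
    out["dmc"] = out["gdmc"]  # region-caller compatibility
    out["direction"] = np.where(
        out["gdmc"] & (out["beta1_adjusted"] > 0),
        "hyper",
        np.where(out["gdmc"], "hypo", "none"),
    )
    return out
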