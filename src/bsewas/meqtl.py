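"""cis-meQTL mapping on arcsine-transformed methylation proportions.

SNP QC keeps well-imputed common variants (INFO > 0.4, MAF > 0.05, both
strict) and removes multiallelic records and coordinate/ID clashes (both
members of a clash are dropped).  Each retained SNP is paired with every
CpG within 250 kbp on the same chromosome, and for each pair the
variance-stabilized proportion y = arcsin(sqrt(M/N)) is regressed on the
allelic dosage plus age, sex, current smoking and the cell-composition PC1
by ordinary least squares (the transform deliberately ignores read depth,
trading power for a fast linear scan).  The dosage coefficient's t-test
p-values receive FDR q-values over the full pair universe on a single
scale; q < 0.01 flags a cis-meQTL.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

from .ewas import build_nuisance
from .qvalues import compute_qvalues
from .types import GenotypeMatrix, MethylationMatrix

log = logging.getLogger(__name__)

CIS_WINDOW = 250_000


def filter_snps(
    geno: GenotypeMatrix, maf_min: float = 0.05, info_min: float = 0.4
) -> GenotypeMatrix:
    """Strict MAF/INFO thresholds plus multiallelic and clash removal."""
    snps = geno.snps
    multi = snps["alt"].str.contains(",")
    pos_dup = snps.duplicated(subset=["chrom", "pos"], keep=False)
    id_dup = snps.duplicated(subset=["id"], keep=False)
    keep = (
        (snps["maf"] > maf_min)
        & (snps["info"] > info_min)
        & ~multi
        & ~pos_dup
        & ~id_dup
    ).to_numpy()
    n_drop = int((~keep).sum())
    if n_drop:
        log.info("SNP QC dropped %d of %d variants", n_drop, len(snps))
    return geno.subset_snps(keep)


def arcsine_transform(m: np.ndarray, n: np.ndarray) -> np.ndarray:
    """y = arcsin(sqrt(m/n)); NaN where n == 0 (excluded pairwise later)."""
    m = np.asarray(m, dtype=float)
    n = np.asarray(n, dtype=float)
    if (m > n).any():
        raise ValueError("methylated count exceeds total count")
    with np.errstate(divide="ignore", invalid="ignore"):
        p = np.where(n > 0, m / np.maximum(n, 1), np.nan)
    return np.arcsin(np.sqrt(p))


def enumerate_cis_pairs(
    mat: MethylationMatrix, geno: GenotypeMatrix, window: int = CIS_WINDOW
) -> pd.DataFrame:
    """All (site, snp) index pairs on the same chromosome within the cis
    window, boundary inclusive at exactly ``window`` bp."""
    snps = geno.snps
    out_site, out_snp = [], []
    for chrom in pd.unique(mat.chrom):
        site_idx = np.where(mat.chrom == chrom)[0]
        snp_idx = np.where((snps["chrom"] == chrom).to_numpy())[0]
        if len(site_idx) == 0 or len(snp_idx) == 0:
            continue
        site_pos = mat.pos[site_idx]
        snp_pos = snps["pos"].to_numpy()[snp_idx]
        order = np.argsort(snp_pos)
        snp_idx, snp_pos = snp_idx[order], snp_pos[order]
        lo = np.searchsorted(snp_pos, site_pos - window, side="left")
        hi = np.searchsorted(snp_pos, site_pos + window, side="right")
        for k, (a, b) in enumerate(zip(lo, hi)):
            out_site.extend([site_idx[k]] * (b - a))
            out_snp.extend(snp_idx[a:b].tolist())
    return pd.DataFrame({"site_idx": out_site, "snp_idx": out_snp})


def scan_meqtl(
    pairs: pd.DataFrame,
    mat: MethylationMatrix,
    geno: GenotypeMatrix,
    covariates: pd.DataFrame,
    q_threshold: float = 0.01,
    q_method: str = "storey",
) -> pd.DataFrame:
    """OLS scan of every cis pair; one FDR scale over all tested pairs.

    Samples with no reads at a site are dropped pairwise.  Pairs with a
    constant dosage over the usable samples, or with fewer usable samples
    than coefficients + 1, are skipped (logged).
    """
    cov = covariates.set_index("sample_id").loc[mat.samples].reset_index()
    # meQTL models share the EWAS nuisance covariates (age, sex, smoking, PC1)
    Z = build_nuisance(cov).to_numpy()
    y_all = arcsine_transform(mat.M, mat.N)
    rows = []
    n_skipped = 0
    for site_idx, group in pairs.groupby("site_idx", sort=True):
        y = y_all[site_idx]
        usable = ~np.isnan(y)
        k_coef = Z.shape[1] + 1
        if usable.sum() < k_coef + 1:
            n_skipped += len(group)
            continue
        yy = y[usable]
        Zu = Z[usable]
        for snp_idx in group["snp_idx"].to_numpy():
            d = geno.dosage[snp_idx][usable]
            if d.min() == d.max():
                n_skipped += 1
                continue
            X = np.column_stack([Zu, d])
            beta, _, rank, _ = np.linalg.lstsq(X, yy, rcond=None)
            if rank < X.shape[1]:
                n_skipped += 1
                continue
            resid = yy - X @ beta
            dof = len(yy) - X.shape[1]
            sigma2 = resid @ resid / dof
            xtx_inv = np.linalg.inv(X.T @ X)
            se = np.sqrt(sigma2 * xtx_inv[-1, -1])
            t = beta[-1] / se
            p = float(2.0 * stats.t.sf(abs(t), dof))
            rows.append(
                {
                    "chrom": mat.chrom[site_idx],
                    "pos": int(mat.pos[site_idx]),
                    "snp_id": geno.snps["id"].iloc[snp_idx],
                    "snp_pos": int(geno.snps["pos"].iloc[snp_idx]),
                    "site_idx": int(site_idx),
                    "snp_idx": int(snp_idx),
                    "beta_snp": float(beta[-1]),
                    "p": p,
                }
            )
    if n_skipped:
        log.info("meQTL scan skipped %d degenerate pairs", n_skipped)
    result = pd.DataFrame(
        rows,
        columns=["chrom", "pos", "snp_id", "snp_pos", "site_idx", "snp_idx",
                 "beta_snp", "p"],
    )
    if len(result):
        result["q"] = compute_qvalues(result["p"].to_numpy(), method=q_method)
        result["is_meqtl"] = result["q"] < q_threshold
    else:
        result["q"] = pd.Series(dtype=float)
        result["is_meqtl"] = pd.Series(dtype=bool)
    return result
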