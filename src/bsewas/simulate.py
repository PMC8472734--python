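"""Synthetic targeted-bisulfite-sequencing cohort generator.

Emulates the statistical structure the analysis assumes: clustered CpG
positions, heavy-tailed read depths (negative-binomial with per-sample
multipliers, matching the 7x vs 27x regimes of capture sequencing),
binomial — optionally beta-binomial — methylated counts whose logit means
carry phenotype, covariate, and cis-SNP dosage effects, planted DMRs
(contiguous runs of sites with a common phenotype effect), planted
cis-meQTLs within the 250 kbp window, and an optional SNP -> phenotype
confounding path that produces marginal methylation-phenotype association
with no direct effect.

Defaults mirror the cohort the models were built for: n = 104 with ~48%
phenotype-positive, age ~ Normal(54.2, 7.9), 55% female, 16% current
smokers, Dirichlet blood-cell proportions centered on whole-blood means
(neutrophil 0.60, lymphocyte 0.29, monocyte 0.08, eosinophil 0.025,
basophil 0.006), and mean depth 30x.

One global seed feeds named independent substreams (sites/depths/
genotypes/covariates/phenotype/counts) so that, e.g., changing the depth
model leaves the genotypes untouched.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .ewas import compute_celltype_pc1
from .io import write_covariates, write_methylation_counts, write_vcf, ensure_outdir
from .types import GenotypeMatrix, MethylationMatrix, ValidationError

CELL_MEANS = np.array([0.079, 0.286, 0.604, 0.025, 0.006])


@dataclass
class SimulationConfig:
    n_samples: int = 104
    n_chroms: int = 2
    # site spacing: clusters of CpGs along each chromosome
    n_clusters_per_chrom: int = 100
    cluster_size: int = 10
    intra_cluster_gap: int = 50
    inter_cluster_gap: int = 5000
    # depth model
    depth_mean: float = 30.0
    depth_size: float = 10.0  # negative-binomial size (smaller = heavier tail)
    sample_depth_log_sd: float = 0.2
    # baseline methylation mixture on the logit scale (low/mid/high)
    baseline_logit_means: tuple[float, float, float] = (-3.0, 0.0, 3.0)
    baseline_logit_sds: tuple[float, float, float] = (0.5, 0.8, 0.5)
    baseline_weights: tuple[float, float, float] = (0.35, 0.10, 0.55)
    # phenotype & covariates
    phenotype_prevalence: float = 50 / 104
    ra_prevalence: float = 8 / 112
    female_prevalence: float = 0.554
    current_smoker_prevalence: float = 0.161
    age_mean: float = 54.2
    age_sd: float = 7.9
    cell_concentration: float = 150.0  # Dirichlet precision around CELL_MEANS
    beta_age: float = 0.005
    beta_sex: float = 0.05
    beta_smoking: float = 0.1
    beta_pc1: float = 0.5
    # planted differential methylation
    n_dmrs: int = 0
    dmr_width: int = 10
    dmr_effect: float = 1.5
    dmr_directions: str = "alternate"  # 'alternate' | 'hyper' | 'hypo'
    # over-dispersion (beta-binomial intra-class correlation; 0 = binomial)
    rho: float = 0.0
    # genotypes
    n_background_snps: int = 0
    maf_range: tuple[float, float] = (0.05, 0.5)
    n_meqtl: int = 0
    meqtl_effect: float = 0.8
    meqtl_max_offset: int = 250_000
    confound_coef: float = 0.0  # SNP -> phenotype log-odds per dosage
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.rho < 1:
            raise ValidationError("rho must be in [0, 1)")
        if not 0 < self.phenotype_prevalence < 1:
            raise ValidationError("phenotype prevalence must be in (0, 1)")
        if self.dmr_width > self.cluster_size:
            raise ValidationError("dmr_width cannot exceed cluster_size")
        if self.n_dmrs + self.n_meqtl > self.n_chroms * self.n_clusters_per_chrom:
            raise ValidationError("more planted clusters than available")

    @property
    def n_sites(self) -> int:
        return self.n_chroms * self.n_clusters_per_chrom * self.cluster_size


def _substreams(seed: int) -> dict[str, np.random.Generator]:
    names = ["sites", "depths", "genotypes", "covariates", "phenotype", "counts"]
    children = np.random.SeedSequence(seed).spawn(len(names))
    return {n: np.random.default_rng(s) for n, s in zip(names, children)}


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def _beta_binomial(rng: np.random.Generator, n: np.ndarray, p: np.ndarray,
                   rho: float) -> np.ndarray:
    a = p * (1 - rho) / rho
    b = (1 - p) * (1 - rho) / rho
    theta = rng.beta(np.maximum(a, 1e-8), np.maximum(b, 1e-8))
    return rng.binomial(n, theta)


def simulate_cohort(
    config: SimulationConfig,
) -> tuple[MethylationMatrix, GenotypeMatrix, pd.DataFrame, pd.DataFrame]:
    """Generate (methylation, genotypes, covariates, truth table).

    The truth table has one row per site: the true phenotype effect,
    planted-DMR id (or -1) and any causal cis-SNP ids with their logit
    effects per dosage.
    """
    cfg = config
    rng = _substreams(cfg.seed)
    n = cfg.n_samples

    # --- site coordinates: clusters along chromosomes -------------------
    chroms, pos = [], []
    cluster_first_idx = []
    cursor = 0
    for c in range(cfg.n_chroms):
        chrom = f"chr{c + 1}"
        x = 1_000_000
        for _ in range(cfg.n_clusters_per_chrom):
            cluster_first_idx.append(cursor)
            for _ in range(cfg.cluster_size):
                chroms.append(chrom)
                pos.append(x)
                x += cfg.intra_cluster_gap
                cursor += 1
            x += cfg.inter_cluster_gap
    chroms = np.array(chroms, dtype=object)
    pos = np.array(pos, dtype=np.int64)
    n_sites = len(pos)

    # --- baseline methylation mixture -----------------------------------
    comp = rng["sites"].choice(3, size=n_sites, p=np.asarray(cfg.baseline_weights))
    base_logit = rng["sites"].normal(
        np.asarray(cfg.baseline_logit_means)[comp],
        np.asarray(cfg.baseline_logit_sds)[comp],
    )

    # --- covariates ------------------------------------------------------
    age = rng["covariates"].normal(cfg.age_mean, cfg.age_sd, size=n)
    sex = np.where(rng["covariates"].random(n) < cfg.female_prevalence,
                   "female", "male")
    smoke_draw = rng["covariates"].random(n)
    smoking = np.select(
        [smoke_draw < cfg.current_smoker_prevalence,
         smoke_draw < cfg.current_smoker_prevalence + 0.43,
         smoke_draw < cfg.current_smoker_prevalence + 0.43 + 0.036],
        ["current", "past", "never"],
        default="missing",
    )
    cell_props = rng["covariates"].dirichlet(
        CELL_MEANS * cfg.cell_concentration, size=n
    )
    pc1, _ = compute_celltype_pc1(cell_props)

    # --- planted effects -------------------------------------------------
    true_beta1 = np.zeros(n_sites)
    dmr_id = np.full(n_sites, -1)
    planted_clusters = rng["sites"].choice(
        len(cluster_first_idx), size=cfg.n_dmrs + cfg.n_meqtl, replace=False
    )
    dmr_clusters = planted_clusters[: cfg.n_dmrs]
    meqtl_clusters = planted_clusters[cfg.n_dmrs:]
    for d, cl in enumerate(dmr_clusters):
        first = cluster_first_idx[cl]
        sign = {"hyper": 1.0, "hypo": -1.0}.get(
            cfg.dmr_directions, 1.0 if d % 2 == 0 else -1.0
        )
        sl = slice(first, first + cfg.dmr_width)
        true_beta1[sl] = sign * cfg.dmr_effect
        dmr_id[sl] = d

    # --- genotypes -------------------------------------------------------
    snp_rows, snp_dosage = [], []
    causal_snp: dict[int, list[tuple[str, float]]] = {}
    geno_rng = rng["genotypes"]
    all_pos_by_chrom = {c: pos[chroms == c] for c in np.unique(chroms)}
    for j, cl in enumerate(meqtl_clusters):
        site_idx = cluster_first_idx[cl]
        maf = geno_rng.uniform(*cfg.maf_range)
        offset = int(geno_rng.integers(500, cfg.meqtl_max_offset))
        snp_pos = int(pos[site_idx]) + offset * (1 if geno_rng.random() < 0.5 else -1)
        sid = f"meqtl_snp_{j}"
        snp_rows.append(
            {"id": sid, "chrom": chroms[site_idx], "pos": max(snp_pos, 1),
             "ref": "A", "alt": "G", "maf": maf,
             "info": float(geno_rng.uniform(0.7, 1.0))}
        )
        snp_dosage.append(geno_rng.binomial(2, maf, size=n).astype(float))
        # the whole cluster is under the SNP's cis influence
        sl = slice(site_idx, site_idx + cfg.cluster_size)
        for k in range(sl.start, sl.stop):
            causal_snp.setdefault(k, []).append((sid, cfg.meqtl_effect))
    for j in range(cfg.n_background_snps):
        maf = geno_rng.uniform(*cfg.maf_range)
        chrom = f"chr{int(geno_rng.integers(1, cfg.n_chroms + 1))}"
        cpos = all_pos_by_chrom[chrom]
        snp_pos = int(geno_rng.integers(int(cpos.min()), int(cpos.max()) + 1))
        snp_rows.append(
            {"id": f"bg_snp_{j}", "chrom": chrom, "pos": snp_pos,
             "ref": "C", "alt": "T", "maf": maf,
             "info": float(geno_rng.uniform(0.7, 1.0))}
        )
        snp_dosage.append(geno_rng.binomial(2, maf, size=n).astype(float))
    snps = pd.DataFrame(
        snp_rows, columns=["id", "chrom", "pos", "ref", "alt", "maf", "info"]
    )
    # de-duplicate coincidental coordinate clashes among background SNPs
    if len(snps):
        keep = ~snps.duplicated(subset=["chrom", "pos"], keep="first")
        snps = snps[keep].reset_index(drop=True)
        snp_dosage = [d for d, k in zip(snp_dosage, keep) if k]
    dosage = np.array(snp_dosage) if snp_dosage else np.empty((0, n))
    sample_ids = [f"S{i:03d}" for i in range(n)]
    geno = GenotypeMatrix(snps=snps, samples=sample_ids, dosage=dosage)

    # --- phenotype (optionally confounded by meQTL SNP dosages) ----------
    logit_prev = np.log(cfg.phenotype_prevalence / (1 - cfg.phenotype_prevalence))
    pheno_logit = np.full(n, logit_prev)
    if cfg.confound_coef != 0.0 and len(meqtl_clusters):
        conf = dosage[: len(meqtl_clusters)].sum(axis=0)
        pheno_logit = pheno_logit + cfg.confound_coef * (conf - conf.mean())
    acpa = np.where(
        rng["phenotype"].random(n) < _sigmoid(pheno_logit), "positive", "negative"
    )
    if len(set(acpa)) == 1:  # degenerate draw at tiny n: force both groups
        acpa[0] = "positive" if acpa[0] == "negative" else "negative"
    ra = np.where(rng["phenotype"].random(n) < cfg.ra_prevalence, "yes", "no")
    if (ra == "yes").sum() == 0:
        ra[0] = "yes"

    covariates = pd.DataFrame(
        {
            "sample_id": sample_ids,
            "age": age,
            "sex": sex,
            "smoking": smoking,
            "monocyte": cell_props[:, 0],
            "lymphocyte": cell_props[:, 1],
            "neutrophil": cell_props[:, 2],
            "eosinophil": cell_props[:, 3],
            "basophil": cell_props[:, 4],
            "acpa": acpa,
            "ra": ra,
        }
    )

    # --- depths ----------------------------------------------------------
    mult = np.exp(rng["depths"].normal(0.0, cfg.sample_depth_log_sd, size=n))
    mu = cfg.depth_mean * mult  # per-sample mean depth
    r = cfg.depth_size
    N = rng["depths"].negative_binomial(
        r, r / (r + mu[None, :]), size=(n_sites, n)
    )

    # --- methylated counts -----------------------------------------------
    acpa_num = (acpa == "positive").astype(float)
    sex_num = (sex == "female").astype(float)
    smoke_num = (smoking == "current").astype(float)
    sample_term = (
        cfg.beta_age * (age - cfg.age_mean)
        + cfg.beta_sex * sex_num
        + cfg.beta_smoking * smoke_num
        + cfg.beta_pc1 * pc1
    )
    logit_p = base_logit[:, None] + true_beta1[:, None] * acpa_num[None, :]
    logit_p = logit_p + sample_term[None, :]
    for k, snp_list in causal_snp.items():
        for sid, eff in snp_list:
            snp_row = snps.index[snps["id"] == sid]
            if len(snp_row):
                logit_p[k] += eff * dosage[snp_row[0]]
    # genotype-driven CpGs show the classic intermediate three-cluster
    # pattern: center each causal site so its population-mean methylation
    # sits near 0.5 given the SNP effects (base = -sum eff * 2 * maf)
    for k, snp_list in causal_snp.items():
        shift = 0.0
        for sid, eff in snp_list:
            snp_row = snps.index[snps["id"] == sid]
            if len(snp_row):
                shift += eff * 2.0 * float(snps["maf"].iloc[snp_row[0]])
        logit_p[k] += -base_logit[k] - shift
    p = _sigmoid(logit_p)
    if cfg.rho > 0:
        M = _beta_binomial(rng["counts"], N, p, cfg.rho)
    else:
        M = rng["counts"].binomial(N, p)

    mat = MethylationMatrix(chrom=chroms, pos=pos, samples=sample_ids, M=M, N=N)
    truth = pd.DataFrame(
        {
            "chrom": chroms,
            "pos": pos,
            "true_beta1": true_beta1,
            "dmr_id": dmr_id,
            "causal_snps": [
                ",".join(s for s, _ in causal_snp.get(k, [])) for k in range(n_sites)
            ],
            "causal_effects": [
                ",".join(f"{e:g}" for _, e in causal_snp.get(k, []))
                for k in range(n_sites)
            ],
        }
    )
    return mat, geno, covariates, truth


def true_regions(truth: pd.DataFrame) -> list[tuple[str, int, int]]:
    """Planted DMR intervals (chrom, first pos, last pos) from a truth table."""
    out = []
    for d, grp in truth[truth["dmr_id"] >= 0].groupby("dmr_id"):
        out.append((grp["chrom"].iloc[0], int(grp["pos"].min()), int(grp["pos"].max())))
    return out


def export_cohort(
    mat: MethylationMatrix,
    geno: GenotypeMatrix,
    covariates: pd.DataFrame,
    truth: pd.DataFrame,
    out_dir,
    overwrite: bool = False,
) -> dict[str, str]:
    """Write counts TSV, VCF, covariates TSV and truth TSV into a directory."""
    out = ensure_outdir(out_dir, overwrite=overwrite)
    paths = {
        "counts": str(out / "counts.tsv"),
        "vcf": str(out / "genotypes.vcf"),
        "covariates": str(out / "covariates.tsv"),
        "truth": str(out / "truth.tsv"),
    }
    write_methylation_counts(mat, paths["counts"])
    write_vcf(geno, paths["vcf"])
    write_covariates(covariates, paths["covariates"])
    truth.to_csv(paths["truth"], sep="\t", index=False)
    return paths


def config_from_dict(d: dict) -> SimulationConfig:
    known = {f for f in SimulationConfig.__dataclass_fields__}
    unknown = set(d) - known
    if unknown:
        raise ValidationError(f"unknown simulation config keys: {sorted(unknown)}")
    d = dict(d)
    for key in ("baseline_logit_means", "baseline_logit_sds", "baseline_weights",
                "maf_range"):
        if key in d and isinstance(d[key], list):
            d[key] = tuple(d[key])
    return SimulationConfig(**d)
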