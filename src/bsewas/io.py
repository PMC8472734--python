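"""Readers and writers for the pipeline's file formats.

Methylation counts travel as a TSV with one row per CpG (columns ``chrom``,
``pos``, then ``<sample>_M`` / ``<sample>_N`` pairs).  Genotypes are VCF with
per-sample GT and/or DS fields; dosages take precedence over hard calls.
Result tables (site results, regions, meQTL pairs) are plain TSVs with a
fixed column order and deterministic (chrom, pos) row ordering, so that
write -> read is the identity.
"""

from __future__ import annotations

import os
from pathlib import Path

import numpy as np
import pandas as pd
from cyvcf2 import VCF

from .types import (
    GenotypeMatrix,
    MethylationMatrix,
    ValidationError,
    site_order,
    validate_covariates,
)

# ---------------------------------------------------------------------------
# methylation counts
# ---------------------------------------------------------------------------


def read_methylation_counts(path: str | Path) -> MethylationMatrix:
    """Read a counts TSV (``chrom``, ``pos``, ``<id>_M``, ``<id>_N`` ...).

    Rows violating 0 <= M <= N raise; duplicates raise.  Line numbers in
    error messages refer to the file including its header line.
    """
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    if df.columns[0] != "chrom" or df.columns[1] != "pos":
        raise ValidationError(f"{path}: first two columns must be chrom, pos")
    value_cols = list(df.columns[2:])
    samples: list[str] = []
    for col in value_cols:
        if col.endswith("_M"):
            sid = col[:-2]
            if f"{sid}_N" not in df.columns:
                raise ValidationError(f"{path}: column {sid}_N missing")
            samples.append(sid)
        elif not col.endswith("_N"):
            raise ValidationError(f"{path}: unrecognized column {col!r}")
    M = df[[f"{s}_M" for s in samples]].to_numpy()
    N = df[[f"{s}_N" for s in samples]].to_numpy()
    if not (np.issubdtype(M.dtype, np.integer) and np.issubdtype(N.dtype, np.integer)):
        raise ValidationError(f"{path}: counts must be integers")
    bad = (M < 0) | (N < 0) | (M > N)
    if bad.any():
        row = int(np.where(bad.any(axis=1))[0][0])
        raise ValidationError(
            f"{path}: line {row + 2}: methylated count outside [0, N]"
        )
    dup = df.duplicated(subset=["chrom", "pos"])
    if dup.any():
        row = int(np.where(dup)[0][0])
        raise ValidationError(f"{path}: line {row + 2}: duplicate (chrom, pos)")
    chroms = df["chrom"].to_numpy(dtype=object)
    pos = df["pos"].to_numpy(dtype=np.int64)
    order = site_order(chroms, pos)
    return MethylationMatrix(
        chrom=chroms[order], pos=pos[order], samples=samples, M=M[order], N=N[order]
    )


def write_methylation_counts(mat: MethylationMatrix, path: str | Path) -> None:
    cols: dict[str, np.ndarray] = {"chrom": mat.chrom, "pos": mat.pos}
    for j, s in enumerate(mat.samples):
        cols[f"{s}_M"] = mat.M[:, j]
        cols[f"{s}_N"] = mat.N[:, j]
    pd.DataFrame(cols).to_csv(path, sep="\t", index=False)


def read_bedgraph_counts(paths: dict[str, str | Path]) -> MethylationMatrix:
    """Convert per-sample bedGraph-style count files (chrom, start0, end,
    methylated, total) into a single matrix; absent sites get N = 0."""
    frames = []
    for sid, p in paths.items():
        df = pd.read_csv(
            p, sep="\t", header=None, names=["chrom", "start", "end", "m", "n"],
            dtype={"chrom": str},
        )
        df["pos"] = df["start"] + 1  # bedGraph is 0-based half-open
        df["sample"] = sid
        frames.append(df[["chrom", "pos", "sample", "m", "n"]])
    long = pd.concat(frames, ignore_index=True)
    m_wide = long.pivot_table(index=["chrom", "pos"], columns="sample", values="m",
                              fill_value=0, aggfunc="first")
    n_wide = long.pivot_table(index=["chrom", "pos"], columns="sample", values="n",
                              fill_value=0, aggfunc="first")
    samples = list(paths)
    m_wide = m_wide[samples]
    n_wide = n_wide[samples]
    chroms = m_wide.index.get_level_values(0).to_numpy(dtype=object)
    pos = m_wide.index.get_level_values(1).to_numpy(dtype=np.int64)
    order = site_order(chroms, pos)
    return MethylationMatrix(
        chrom=chroms[order],
        pos=pos[order],
        samples=samples,
        M=m_wide.to_numpy(dtype=np.int64)[order],
        N=n_wide.to_numpy(dtype=np.int64)[order],
    )


# ---------------------------------------------------------------------------
# covariates
# ---------------------------------------------------------------------------


def read_covariates(path: str | Path) -> pd.DataFrame:
    cov = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    return validate_covariates(cov)


def write_covariates(cov: pd.DataFrame, path: str | Path) -> None:
    validate_covariates(cov).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# genotypes (VCF)
# ---------------------------------------------------------------------------


def read_genotypes(path: str | Path) -> GenotypeMatrix:
    """Read a VCF into a dosage matrix.

    Dosage is the DS FORMAT value when present, otherwise the alt-allele
    count from GT.  MAF comes from the INFO AF field (minor-allele folded)
    when present, otherwise from the mean dosage; the imputation quality
    score is read from INFO key ``INFO`` (1.0 when absent).
    """
    vcf = VCF(str(path))
    samples = list(vcf.samples)
    rows, dosages = [], []
    for var in vcf:
        try:
            ds = var.format("DS")
        except KeyError:  # DS absent from the header entirely
            ds = None
        if ds is not None:
            d = np.asarray(ds, dtype=float).reshape(-1)
        else:
            gts = var.genotype.array()
            if gts is None:
                raise ValidationError(f"{path}: {var.ID}: neither DS nor GT present")
            alleles = np.asarray(gts)[:, :2]
            d = (alleles > 0).sum(axis=1).astype(float)
            d[(alleles < 0).any(axis=1)] = np.nan
        try:
            af = var.INFO.get("AF")
        except KeyError:
            af = None
        if af is None:
            mean = float(np.nanmean(d))
            af = mean / 2.0
        maf = min(float(af), 1.0 - float(af))
        try:
            info = var.INFO.get("INFO")
        except KeyError:
            info = None
        info = 1.0 if info is None else float(info)
        alts = var.ALT
        alt = alts[0] if len(alts) == 1 else ",".join(alts)  # multiallelic kept for QC stage
        chrom = var.CHROM if var.CHROM.startswith("chr") else f"chr{var.CHROM}"
        rows.append(
            {
                "id": var.ID or f"{chrom}:{var.POS}",
                "chrom": chrom,
                "pos": var.POS,
                "ref": var.REF,
                "alt": alt,
                "maf": maf,
                "info": info,
            }
        )
        dosages.append(np.clip(np.nan_to_num(d, nan=float(np.nanmean(d))), 0.0, 2.0))
    snps = pd.DataFrame(rows, columns=["id", "chrom", "pos", "ref", "alt", "maf", "info"])
    return GenotypeMatrix(snps=snps, samples=samples, dosage=np.array(dosages))


def write_vcf(geno: GenotypeMatrix, path: str | Path) -> None:
    """Write a plain-text VCF 4.2 with GT (rounded) and DS per sample."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##INFO=<ID=AF,Number=A,Type=Float,Description="Allele frequency">\n')
        fh.write('##INFO=<ID=INFO,Number=1,Type=Float,Description="Imputation info score">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=DS,Number=1,Type=Float,Description="Alt dosage">\n')
        for i in range(1, 23):
            fh.write(f"##contig=<ID=chr{i}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(geno.samples)
            + "\n"
        )
        order = site_order(
            geno.snps["chrom"].to_numpy(dtype=object), geno.snps["pos"].to_numpy()
        )
        gt_codes = {0: "0/0", 1: "0/1", 2: "1/1"}
        for i in order:
            snp = geno.snps.iloc[i]
            af = snp["maf"]  # simulated alt allele is the minor allele
            fields = [
                str(snp["chrom"]),
                str(int(snp["pos"])),
                str(snp["id"]),
                str(snp["ref"]),
                str(snp["alt"]),
                ".",
                "PASS",
                f"AF={af:.6g};INFO={snp['info']:.6g}",
                "GT:DS",
            ]
            for d in geno.dosage[i]:
                gt = gt_codes[int(round(d))]
                fields.append(f"{gt}:{d:.6g}")
            fh.write("\t".join(fields) + "\n")


# ---------------------------------------------------------------------------
# result tables
# ---------------------------------------------------------------------------

SITE_RESULT_COLUMNS = [
    "chrom", "pos", "beta0", "beta1", "beta2", "beta3", "beta4", "beta5",
    "se1", "wald_p", "q", "converged", "dmc", "direction",
]

REGION_COLUMNS = ["chrom", "start", "end", "n_sites", "direction", "members"]

MEQTL_COLUMNS = ["chrom", "pos", "snp_id", "snp_pos", "beta_snp", "p", "q", "is_meqtl"]


def _sorted_by_site(table: pd.DataFrame, pos_col: str) -> pd.DataFrame:
    order = site_order(
        table["chrom"].to_numpy(dtype=object), table[pos_col].to_numpy()
    )
    return table.iloc[order].reset_index(drop=True)


def write_results(table: pd.DataFrame, path: str | Path) -> None:
    """Write a results table (site results, regions, or meQTL pairs) as TSV.

    The table kind is inferred from its columns; rows are emitted in
    deterministic (chrom, position) order, floats at full precision.
    """
    cols = set(table.columns)
    if set(REGION_COLUMNS) <= cols:
        out = _sorted_by_site(table[REGION_COLUMNS].copy(), "start")
    elif set(MEQTL_COLUMNS) <= cols:
        out = _sorted_by_site(table[MEQTL_COLUMNS].copy(), "pos")
    elif {"chrom", "pos"} <= cols:
        ordered = [c for c in SITE_RESULT_COLUMNS if c in cols]
        ordered += [c for c in table.columns if c not in ordered]
        out = _sorted_by_site(table[ordered].copy(), "pos")
    else:
        raise ValidationError("unrecognized results table (no chrom/pos columns)")
    out.to_csv(path, sep="\t", index=False, float_format="%.17g")


def read_results(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    if "members" in df.columns:
        df["members"] = df["members"].map(
            lambda s: [int(x) for x in str(s).split(",")] if pd.notna(s) and s != "" else []
        )
    return df


# ---------------------------------------------------------------------------
# gene models & GWAS catalog
# ---------------------------------------------------------------------------

GENE_MODEL_COLUMNS = ["gene_id", "symbol", "chrom", "strand", "tss", "start", "end", "biotype"]


def read_gene_models(path: str | Path) -> pd.DataFrame:
    """Read a gene-model TSV (gene_id, symbol, chrom, strand, tss, start,
    end, biotype); body intervals are half-open 0-based [start, end)."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "strand": str})
    missing = set(GENE_MODEL_COLUMNS) - set(df.columns)
    if missing:
        raise ValidationError(f"gene-model table missing columns: {sorted(missing)}")
    bad = ~((df["tss"] >= df["start"]) & (df["tss"] <= df["end"]))
    if bad.any():
        raise ValidationError("gene body must contain the TSS")
    if not df["strand"].isin(["+", "-"]).all():
        raise ValidationError("strand must be + or -")
    return df


GWAS_EXPORT_COLUMNS = {
    "SNPS": "rsid",
    "CHR_ID": "chrom",
    "CHR_POS": "pos",
    "P-VALUE": "p",
    "MAPPED_GENE": "mapped_genes",
    "MAPPED_TRAIT": "trait",
}


def read_gwas_catalog(path: str | Path) -> pd.DataFrame:
    """Read a GWAS-catalog-style TSV export into the internal schema."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = set(GWAS_EXPORT_COLUMNS) - set(df.columns)
    if missing:
        raise ValidationError(f"GWAS table missing columns: {sorted(missing)}")
    out = df.rename(columns=GWAS_EXPORT_COLUMNS)[list(GWAS_EXPORT_COLUMNS.values())]
    out["p"] = out["p"].astype(float)
    return out


def ensure_outdir(path: str | Path, overwrite: bool = False) -> Path:
    p = Path(path)
    if p.exists() and any(p.iterdir()) and not overwrite:
        raise FileExistsError(f"{p} exists and is not empty (pass overwrite=True)")
    os.makedirs(p, exist_ok=True)
    return p
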