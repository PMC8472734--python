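"""GWAS-catalog filtering and DMR -> gene feature mapping.

Gene features follow the usual TSS-anchored definitions: the promoter is
the 1 kbp window strand-upstream of the TSS, the distal upstream window
covers 1-5 kbp strand-upstream, and the gene body is the full annotated
interval.  All intervals are half-open 0-based internally; a region is
assigned to a gene when any feature overlaps it by at least one basepair.
Regions touching no feature are intergenic and excluded from gene sets, as
are non-protein-coding models.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy.stats import hypergeom

from .types import AUTOSOMES, Region, ValidationError

DEFAULT_EXCLUDED_TRAITS = (
    "ACPA-negative rheumatoid arthritis",
    "ankylosing spondylitis",
    "psoriatic arthritis",
)

GENOME_WIDE_P = 5e-8


def filter_gwas_catalog(
    records: pd.DataFrame,
    excluded_traits: tuple[str, ...] = DEFAULT_EXCLUDED_TRAITS,
    p_max: float = GENOME_WIDE_P,
) -> pd.DataFrame:
    """Keep autosomal SNP-type records at genome-wide significance whose
    trait is not excluded; (rsid, trait) duplicates keep the smallest p."""
    df = records.copy()
    is_snp = df["rsid"].astype(str).str.match(r"rs\d+$")
    chrom = df["chrom"].astype(str).str.replace("chr", "", regex=False)
    autosomal = chrom.isin([c.removeprefix("chr") for c in AUTOSOMES])
    excluded = df["trait"].isin(excluded_traits)
    keep = is_snp & autosomal & ~excluded & (df["p"] <= p_max)
    out = df[keep].sort_values("p", kind="mergesort")
    out = out.drop_duplicates(subset=["rsid", "trait"], keep="first")
    return out.reset_index(drop=True)


@dataclass
class GeneFeatures:
    """Queryable interval index of gene features per chromosome."""

    trees: dict[str, IntervalTree]
    table: pd.DataFrame  # gene_id, symbol, chrom, feature, start, end

    def query(self, chrom: str, start: int, end: int) -> pd.DataFrame:
        """Features overlapping the half-open interval [start, end)."""
        tree = self.trees.get(chrom)
        if tree is None or start >= end:
            return self.table.iloc[0:0]
        hits = sorted(iv.data for iv in tree.overlap(start, end))
        return self.table.iloc[hits]


def build_gene_features(
    models: pd.DataFrame,
    promoter_width: int = 1000,
    upstream_near: int = 1000,
    upstream_far: int = 5000,
) -> GeneFeatures:
    """Build promoter / 1-5 kbp upstream / gene-body interval indexes.

    For a plus-strand gene with TSS t: promoter = [t - 1000, t), distal
    upstream = [t - 5000, t - 1000); minus-strand windows mirror to the
    right of the TSS.  The body is the annotated [start, end).
    """
    rows = []
    for _, g in models.iterrows():
        tss, strand = int(g["tss"]), g["strand"]
        if not (g["start"] <= tss <= g["end"]):
            raise ValidationError(f"{g['gene_id']}: body must contain the TSS")
        if strand == "+":
            promoter = (tss - promoter_width, tss)
            upstream = (tss - upstream_far, tss - upstream_near)
        else:
            promoter = (tss, tss + promoter_width)
            upstream = (tss + upstream_near, tss + upstream_far)
        for feature, (s, e) in (
            ("promoter", promoter),
            ("upstream_1to5kb", upstream),
            ("gene_body", (int(g["start"]), int(g["end"]))),
        ):
            rows.append(
                {
                    "gene_id": g["gene_id"],
                    "symbol": g["symbol"],
                    "chrom": g["chrom"],
                    "biotype": g.get("biotype", "protein_coding"),
                    "feature": feature,
                    "start": max(int(s), 0),
                    "end": int(e),
                }
            )
    table = pd.DataFrame(rows).sort_values(
        ["chrom", "start", "end", "gene_id", "feature"], kind="mergesort"
    ).reset_index(drop=True)
    trees: dict[str, IntervalTree] = {}
    for i, row in table.iterrows():
        if row["end"] <= row["start"]:
            continue
        trees.setdefault(row["chrom"], IntervalTree()).addi(
            row["start"], row["end"], i
        )
    return GeneFeatures(trees=trees, table=table)


def map_regions_to_genes(
    regions: list[Region],
    features: GeneFeatures,
    protein_coding_only: bool = True,
) -> pd.DataFrame:
    """Assign each region to every gene feature it overlaps by >= 1 bp.

    Region coordinates are 1-based inclusive CpG positions; they convert
    to the half-open interval [start - 1, end).  Returns one row per
    (region, gene, feature); regions with no assignment appear once with
    feature 'intergenic' and a null gene.
    """
    rows = []
    for ri, region in enumerate(regions):
        hits = features.query(region.chrom, region.start - 1, region.end)
        if protein_coding_only and len(hits):
            hits = hits[hits["biotype"] == "protein_coding"]
        if len(hits) == 0:
            rows.append(
                {
                    "region_idx": ri, "chrom": region.chrom,
                    "start": region.start, "end": region.end,
                    "direction": region.direction, "gene_id": None,
                    "symbol": None, "feature": "intergenic",
                }
            )
            continue
        for _, h in hits.iterrows():
            rows.append(
                {
                    "region_idx": ri, "chrom": region.chrom,
                    "start": region.start, "end": region.end,
                    "direction": region.direction, "gene_id": h["gene_id"],
                    "symbol": h["symbol"], "feature": h["feature"],
                }
            )
    return pd.DataFrame(
        rows,
        columns=["region_idx", "chrom", "start", "end", "direction",
                 "gene_id", "symbol", "feature"],
    )


def assigned_gene_set(assignments: pd.DataFrame) -> set[str]:
    """Unique normalized symbols of genically assigned regions."""
    genic = assignments[assignments["feature"] != "intergenic"]
    return {normalize_symbol(s) for s in genic["symbol"].dropna()}


def normalize_symbol(symbol: str) -> str:
    """Uppercase and strip trailing version suffixes (e.g. 'Gene.2')."""
    return re.sub(r"\.\d+$", "", str(symbol).strip()).upper()


def gene_set_overlap(set_a: set[str], set_b: set[str]) -> dict:
    shared = sorted(set_a & set_b)
    return {
        "n_a": len(set_a),
        "n_b": len(set_b),
        "n_shared": len(shared),
        "shared": shared,
    }


def hypergeometric_enrichment(
    query: set[str],
    term_sets: dict[str, set[str]],
    background: set[str],
) -> pd.DataFrame:
    """One-sided hypergeometric over-representation test per term with BH
    adjustment across terms (a local stand-in enrichment procedure)."""
    if not query <= background:
        raise ValidationError("query genes must be a subset of the background")
    n_bg, n_query = len(background), len(query)
    rows = []
    for term, genes in term_sets.items():
        genes = genes & background
        k = len(query & genes)
        p = float(hypergeom.sf(k - 1, n_bg, len(genes), n_query))
        rows.append({"term": term, "n_term": len(genes), "n_overlap": k, "p": p})
    out = pd.DataFrame(rows)
    if len(out):
        from .qvalues import compute_qvalues

        out["p_adjusted"] = compute_qvalues(out["p"].to_numpy(), method="bh")
    return out
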