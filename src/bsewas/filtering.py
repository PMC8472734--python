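"""CpG site quality-control filters and coverage summaries.

Sites are restricted to autosomes, invariant sites (all reads methylated or
all unmethylated across every sample) are dropped, and a per-site depth
rule keeps a CpG only when enough samples reach a minimum read depth.
The three filters commute, so the composition order is a matter of
reporting, not of the final site set.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .report import percentage
from .types import AUTOSOMES, MethylationMatrix, ValidationError

log = logging.getLogger(__name__)


@dataclass
class FilterReport:
    n_input: int
    n_after_autosome: int
    n_after_variability: int
    n_after_depth: int
    min_depth: int
    min_samples: int

    def __post_init__(self) -> None:
        counts = [self.n_input, self.n_after_autosome,
                  self.n_after_variability, self.n_after_depth]
        if any(a < b for a, b in zip(counts, counts[1:])):
            raise ValidationError("filter counts must be non-increasing")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "stage": ["input", "autosome", "variability", "depth"],
                "n_sites": [self.n_input, self.n_after_autosome,
                            self.n_after_variability, self.n_after_depth],
            }
        )


def filter_autosomes(mat: MethylationMatrix) -> MethylationMatrix:
    """Keep chr1..chr22 only; unrecognized labels are dropped with a warning."""
    keep = np.array([c in AUTOSOMES for c in mat.chrom])
    dropped = mat.chrom[~keep]
    non_auto = [c for c in set(dropped) if c not in ("chrX", "chrY", "chrM", "chrMT")]
    if non_auto:
        log.warning("dropping %d sites on unrecognized chromosomes %s",
                    sum(c in non_auto for c in dropped), sorted(non_auto))
    if len(dropped):
        log.info("autosome filter dropped %d sites", len(dropped))
    return mat.subset_sites(keep)


def drop_invariant_sites(mat: MethylationMatrix) -> MethylationMatrix:
    """Drop sites where every read is methylated or every read unmethylated
    (sum M == 0 or sum M == sum N across samples): no variability to model."""
    total_m = mat.M.sum(axis=1)
    total_n = mat.N.sum(axis=1)
    keep = (total_m > 0) & (total_m < total_n)
    return mat.subset_sites(keep)


def filter_by_depth(
    mat: MethylationMatrix, min_depth: int = 15, min_samples: int = 30
) -> tuple[MethylationMatrix, pd.Series]:
    """Keep a site iff at least ``min_samples`` samples have depth
    N >= ``min_depth``; also returns the per-site qualifying-sample count."""
    if min_depth < 1 or min_samples < 1:
        raise ValidationError("min_depth and min_samples must be >= 1")
    if min_samples > mat.n_samples:
        raise ValidationError(
            f"min_samples={min_samples} exceeds cohort size {mat.n_samples}"
        )
    qualifying = (mat.N >= min_depth).sum(axis=1)
    keep = qualifying >= min_samples
    return mat.subset_sites(keep), pd.Series(qualifying, name="n_qualifying")


def run_qc(
    mat: MethylationMatrix, min_depth: int = 15, min_samples: int = 30
) -> tuple[MethylationMatrix, FilterReport]:
    """Autosome -> variability -> depth filter chain with a stage report."""
    n0 = mat.n_sites
    auto = filter_autosomes(mat)
    var = drop_invariant_sites(auto)
    deep, _ = filter_by_depth(var, min_depth=min_depth, min_samples=min_samples)
    report = FilterReport(
        n_input=n0,
        n_after_autosome=auto.n_sites,
        n_after_variability=var.n_sites,
        n_after_depth=deep.n_sites,
        min_depth=min_depth,
        min_samples=min_samples,
    )
    return deep, report


def coverage_summary(mat: MethylationMatrix) -> pd.DataFrame:
    """Per-site mean and median read depth across samples."""
    return pd.DataFrame(
        {
            "chrom": mat.chrom,
            "pos": mat.pos,
            "mean_depth": mat.N.mean(axis=1),
            "median_depth": np.median(mat.N, axis=1),
            "null_median": np.median(mat.N, axis=1) == 0,
        }
    )


def compare_coverage(
    summary_a: pd.DataFrame,
    summary_b: pd.DataFrame,
    mean_depth_cutoff: float = 10.0,
) -> pd.DataFrame:
    """Overlap report between two coverage summaries keyed by (chrom, pos).

    Rows give counts with the denominator used and one-decimal half-up
    percentages: shared sites as a fraction of each dataset, and — among
    shared sites — null-median and low-mean-depth fractions per dataset.
    """
    a = summary_a.set_index(["chrom", "pos"])
    b = summary_b.set_index(["chrom", "pos"])
    shared = a.index.intersection(b.index)
    if len(shared) == 0:
        log.warning("coverage comparison: no shared sites")
    rows = []

    def add(name: str, count: int, denom: int) -> None:
        rows.append(
            {
                "metric": name,
                "count": count,
                "denominator": denom,
                "pct": percentage(count, denom) if denom else 0.0,
            }
        )

    add("shared_of_A", len(shared), len(a))
    add("shared_of_B", len(shared), len(b))
    for label, summ in (("A", a), ("B", b)):
        sub = summ.loc[shared]
        add(f"null_median_{label}", int(sub["null_median"].sum()), len(shared))
        add(
            f"mean_depth_below_{mean_depth_cutoff:g}_{label}",
            int((sub["mean_depth"] < mean_depth_cutoff).sum()),
            len(shared),
        )
    return pd.DataFrame(rows)
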