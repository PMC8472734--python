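"""Core in-memory containers for the count-based EWAS pipeline.

Methylation is carried as paired integer matrices of methylated reads ``M``
and total reads ``N`` (sites x samples), the sufficient statistics of the
per-CpG binomial model.  Genotypes are carried as allelic dosages in [0, 2].
Coordinates for CpG sites are 1-based basepair positions; gene-feature
intervals are half-open 0-based and converted at the I/O boundary.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

AUTOSOMES = tuple(f"chr{i}" for i in range(1, 23))

#: canonical covariate columns expected in a sample table
COVARIATE_COLUMNS = (
    "sample_id",
    "age",
    "sex",
    "smoking",
    "monocyte",
    "lymphocyte",
    "neutrophil",
    "eosinophil",
    "basophil",
    "acpa",
    "ra",
)

CELL_TYPES = ("monocyte", "lymphocyte", "neutrophil", "eosinophil", "basophil")


class ValidationError(ValueError):
    """An input violates a container invariant (never silently repaired)."""


def chrom_sort_key(chrom: str) -> tuple[int, str]:
    """Natural ordering: chr1 < chr2 < ... < chr22 < chrX < chrY < chrM < other."""
    m = re.fullmatch(r"(?:chr)?(\d+)", chrom)
    if m:
        return (int(m.group(1)), "")
    special = {"chrX": 23, "X": 23, "chrY": 24, "Y": 24, "chrM": 25, "chrMT": 25, "MT": 25, "M": 25}
    return (special.get(chrom, 99), chrom)


def site_order(chroms: np.ndarray, pos: np.ndarray) -> np.ndarray:
    """Stable argsort of sites by (chrom natural order, position)."""
    keys = [chrom_sort_key(c) for c in chroms]
    return np.array(
        sorted(range(len(pos)), key=lambda i: (keys[i], int(pos[i]))), dtype=int
    )


@dataclass
class MethylationMatrix:
    """Per-site, per-sample methylated (M) and total (N) read counts.

    ``N == 0`` cells mean "no reads at this site in this sample" and are
    valid; downstream fits exclude them sample-wise.
    """

    chrom: np.ndarray  # (n_sites,) str
    pos: np.ndarray  # (n_sites,) int, 1-based
    samples: list[str]
    M: np.ndarray  # (n_sites, n_samples) int
    N: np.ndarray  # (n_sites, n_samples) int

    def __post_init__(self) -> None:
        self.chrom = np.asarray(self.chrom, dtype=object)
        self.pos = np.asarray(self.pos, dtype=np.int64)
        self.M = np.asarray(self.M, dtype=np.int64)
        self.N = np.asarray(self.N, dtype=np.int64)
        self.validate()

    def validate(self) -> None:
        n_sites, n_samples = self.M.shape
        if self.N.shape != (n_sites, n_samples):
            raise ValidationError("M and N shapes differ")
        if len(self.chrom) != n_sites or len(self.pos) != n_sites:
            raise ValidationError("site annotation length mismatch")
        if len(self.samples) != n_samples:
            raise ValidationError("sample list length mismatch")
        if len(set(self.samples)) != n_samples:
            raise ValidationError("duplicate sample IDs")
        if (self.M < 0).any() or (self.N < 0).any():
            raise ValidationError("negative read counts")
        if (self.M > self.N).any():
            raise ValidationError("methylated count exceeds total count")
        keys = list(zip(self.chrom.tolist(), self.pos.tolist()))
        if len(set(keys)) != n_sites:
            raise ValidationError("duplicate (chrom, pos) sites")
        order = site_order(self.chrom, self.pos)
        if not np.array_equal(order, np.arange(n_sites)):
            raise ValidationError("sites not sorted by (chrom, pos)")

    @property
    def n_sites(self) -> int:
        return self.M.shape[0]

    @property
    def n_samples(self) -> int:
        return self.M.shape[1]

    def site_index(self) -> pd.MultiIndex:
        return pd.MultiIndex.from_arrays([self.chrom, self.pos], names=["chrom", "pos"])

    def subset_sites(self, mask: np.ndarray) -> "MethylationMatrix":
        mask = np.asarray(mask)
        return MethylationMatrix(
            chrom=self.chrom[mask],
            pos=self.pos[mask],
            samples=list(self.samples),
            M=self.M[mask],
            N=self.N[mask],
        )

    def proportions(self) -> np.ndarray:
        """M/N with NaN where N == 0."""
        with np.errstate(divide="ignore", invalid="ignore"):
            return np.where(self.N > 0, self.M / np.maximum(self.N, 1), np.nan)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, MethylationMatrix):
            return NotImplemented
        return (
            np.array_equal(self.chrom, other.chrom)
            and np.array_equal(self.pos, other.pos)
            and self.samples == other.samples
            and np.array_equal(self.M, other.M)
            and np.array_equal(self.N, other.N)
        )


@dataclass
class GenotypeMatrix:
    """SNP dosage matrix with per-variant MAF and imputation INFO metadata."""

    snps: pd.DataFrame  # columns: id, chrom, pos, ref, alt, maf, info
    samples: list[str]
    dosage: np.ndarray  # (n_snps, n_samples) float in [0, 2]

    def __post_init__(self) -> None:
        self.dosage = np.asarray(self.dosage, dtype=float)
        self.validate()

    def validate(self) -> None:
        required = {"id", "chrom", "pos", "ref", "alt", "maf", "info"}
        missing = required - set(self.snps.columns)
        if missing:
            raise ValidationError(f"snps table missing columns: {sorted(missing)}")
        if self.dosage.shape != (len(self.snps), len(self.samples)):
            raise ValidationError("dosage shape mismatch")
        if ((self.dosage < 0) | (self.dosage > 2)).any():
            raise ValidationError("dosage outside [0, 2]")
        key = self.snps[["chrom", "pos", "ref", "alt"]].apply(tuple, axis=1)
        if key.duplicated().any():
            raise ValidationError("duplicate (chrom, pos, ref, alt) variants")

    @property
    def n_snps(self) -> int:
        return len(self.snps)

    def subset_snps(self, mask: np.ndarray) -> "GenotypeMatrix":
        mask = np.asarray(mask)
        return GenotypeMatrix(
            snps=self.snps.loc[mask].reset_index(drop=True),
            samples=list(self.samples),
            dosage=self.dosage[mask],
        )


@dataclass
class Region:
    """A differentially methylated region: >= 3 same-direction DMCs with
    consecutive gaps <= the merge distance.  ``start``/``end`` are the 1-based
    positions of the first and last member CpGs (inclusive)."""

    chrom: str
    start: int
    end: int
    direction: str  # 'hyper' | 'hypo'
    members: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.direction not in ("hyper", "hypo"):
            raise ValidationError(f"bad direction {self.direction!r}")
        if self.members != sorted(self.members):
            raise ValidationError("region members not sorted")
        if self.members:
            if self.start != self.members[0] or self.end != self.members[-1]:
                raise ValidationError("region bounds do not match members")
        if self.start > self.end:
            raise ValidationError("region start > end")

    @property
    def n_sites(self) -> int:
        return len(self.members)


def validate_covariates(cov: pd.DataFrame) -> pd.DataFrame:
    """Check a sample covariate table against the expected schema."""
    missing = set(COVARIATE_COLUMNS) - set(cov.columns)
    if missing:
        raise ValidationError(f"covariate table missing columns: {sorted(missing)}")
    if cov["sample_id"].duplicated().any():
        raise ValidationError("duplicate sample IDs in covariate table")
    props = cov[list(CELL_TYPES)].to_numpy(dtype=float)
    if ((props < 0) | (props > 1)).any():
        raise ValidationError("cell proportions outside [0, 1]")
    bad_sex = ~cov["sex"].isin(["female", "male"])
    if bad_sex.any():
        raise ValidationError("sex must be 'female' or 'male'")
    bad_smoke = ~cov["smoking"].isin(["current", "past", "never", "missing"])
    if bad_smoke.any():
        raise ValidationError("smoking must be current/past/never/missing")
    return cov
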