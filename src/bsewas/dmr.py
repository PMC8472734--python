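"""Differentially methylated region (DMR) calling by adjacency merging.

Two DMCs of the same direction are contiguous when they lie within
``max_gap`` basepairs of each other (inclusive); a maximal run of three or
more contiguous same-direction DMCs is a DMR.  The two directions are
merged independently, so hyper- and hypomethylated runs can interleave by
position without breaking each other.  Only maximal runs are emitted: a
region is never split into sub-regions by the caller itself.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .report import percentage
from .types import Region, ValidationError, chrom_sort_key, site_order


def call_regions(
    dmcs: pd.DataFrame, max_gap: int = 200, min_sites: int = 3
) -> list[Region]:
    """Merge flagged DMCs into regions.

    ``dmcs`` must be a site-result table sorted by (chrom, pos) containing
    ``dmc`` and ``direction`` columns; only rows with dmc == True are used.
    """
    flagged = dmcs[dmcs["dmc"]] if "dmc" in dmcs.columns else dmcs
    chroms = flagged["chrom"].to_numpy(dtype=object)
    pos = flagged["pos"].to_numpy(dtype=np.int64)
    order = site_order(chroms, pos)
    if not np.array_equal(order, np.arange(len(pos))):
        raise ValidationError("DMC table must be sorted by (chrom, pos)")
    regions: list[Region] = []
    for direction in ("hyper", "hypo"):
        sel = (flagged["direction"] == direction).to_numpy()
        for chrom in pd.unique(chroms[sel]):
            p = pos[sel & (chroms == chrom)]
            run: list[int] = []
            for x in p:
                if run and x - run[-1] <= max_gap:
                    run.append(int(x))
                else:
                    if len(run) >= min_sites:
                        regions.append(
                            Region(chrom=chrom, start=run[0], end=run[-1],
                                   direction=direction, members=run)
                        )
                    run = [int(x)]
            if len(run) >= min_sites:
                regions.append(
                    Region(chrom=chrom, start=run[0], end=run[-1],
                           direction=direction, members=run)
                )
    regions.sort(key=lambda r: (chrom_sort_key(r.chrom), r.start))
    return regions


def regions_to_frame(regions: list[Region]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "chrom": [r.chrom for r in regions],
            "start": [r.start for r in regions],
            "end": [r.end for r in regions],
            "n_sites": [r.n_sites for r in regions],
            "direction": [r.direction for r in regions],
            "members": [",".join(map(str, r.members)) for r in regions],
        },
        columns=["chrom", "start", "end", "n_sites", "direction", "members"],
    )


def summarize_regions(regions: list[Region], dmcs: pd.DataFrame) -> dict:
    """Counts by direction, size distribution, the largest region, and the
    percentage of DMCs that fall inside regions (one decimal, half-up)."""
    n_dmc = int(dmcs["dmc"].sum()) if "dmc" in dmcs.columns else len(dmcs)
    clustered = sum(r.n_sites for r in regions)
    sizes = np.array([r.n_sites for r in regions], dtype=int)
    largest = max(regions, key=lambda r: r.n_sites) if regions else None
    return {
        "n_regions": len(regions),
        "n_hyper": sum(1 for r in regions if r.direction == "hyper"),
        "n_hypo": sum(1 for r in regions if r.direction == "hypo"),
        "n_dmc": n_dmc,
        "n_dmc_clustered": clustered,
        "pct_dmc_clustered": percentage(clustered, n_dmc) if n_dmc else 0.0,
        "size_counts": dict(zip(*np.unique(sizes, return_counts=True))) if len(sizes) else {},
        "largest_region": largest,
    }
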