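"""Reporting helpers: rounded percentages and run summaries.

All printed percentages use one-decimal half-up rounding (so 36.05 -> 36.1),
the convention followed throughout the result tables.
"""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal

import pandas as pd


def percentage(numerator: float, denominator: float, decimals: int = 1) -> float:
    """100 * numerator / denominator rounded half-up to ``decimals``."""
    if denominator == 0:
        raise ZeroDivisionError("percentage with zero denominator")
    frac = Decimal(numerator) * 100 / Decimal(denominator)
    quantum = Decimal(1).scaleb(-decimals)
    return float(frac.quantize(quantum, rounding=ROUND_HALF_UP))


def model_summary_row(
    model: str,
    n_tested: int,
    site_results: pd.DataFrame,
    regions: list,
) -> dict:
    """One row of the per-model summary table: sites tested, DMC and DMR
    counts with hyper/hypo splits, and the clustered-DMC percentage."""
    dmcs = site_results[site_results["dmc"]]
    n_dmc = len(dmcs)
    n_hyper = int((dmcs["direction"] == "hyper").sum())
    n_hypo = int((dmcs["direction"] == "hypo").sum())
    n_regions = len(regions)
    hyper_regions = sum(1 for r in regions if r.direction == "hyper")
    clustered = sum(r.n_sites for r in regions)
    return {
        "model": model,
        "n_tested": n_tested,
        "n_dmc": n_dmc,
        "n_hyper_dmc": n_hyper,
        "n_hypo_dmc": n_hypo,
        "n_dmr": n_regions,
        "n_hyper_dmr": hyper_regions,
        "n_hypo_dmr": n_regions - hyper_regions,
        "n_dmc_clustered": clustered,
        "pct_dmc_clustered": percentage(clustered, n_dmc) if n_dmc else 0.0,
    }


def render_summary(rows: list[dict]) -> str:
    """Plain-text model summary (one line per fitted model)."""
    df = pd.DataFrame(rows)
    return df.to_string(index=False)
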