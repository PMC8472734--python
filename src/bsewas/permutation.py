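"""Permutation tests for agreement between two CpG site sets.

Set B is held fixed while set A is replaced by uniform resamples of the
same size drawn (without replacement) from a user-supplied universe — the
sites tested in both analyses.  Two evaluation statistics are offered:
the number of exact-position overlaps (upper-tailed) and the mean distance
from each A site to the nearest B site on the same chromosome
(lower-tailed, directional A -> B).  Empirical p-values use the plus-one
estimator (1 + #extreme) / (1 + n_perm), so p is never exactly zero.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

log = logging.getLogger(__name__)

Site = tuple[str, int]


@dataclass
class PermutationResult:
    statistic: str
    observed: float
    null: np.ndarray
    p_value: float
    tail: str
    n_perm: int
    seed: int


def num_overlaps(a: set[Site], b: set[Site]) -> int:
    """Exact-position overlap count |A ∩ B| (symmetric)."""
    return len(a & b)


def mean_nearest_distance(a: set[Site], b: set[Site]) -> float:
    """Mean over a in A of the distance to the closest b on a's chromosome.

    A-sites on chromosomes with no B-sites are excluded (logged).
    Directional: mean_nearest_distance(A, B) != mean_nearest_distance(B, A).
    """
    b_by_chrom: dict[str, np.ndarray] = {}
    for chrom, pos in b:
        b_by_chrom.setdefault(chrom, []).append(pos)  # type: ignore[arg-type]
    b_by_chrom = {c: np.sort(np.array(p)) for c, p in b_by_chrom.items()}
    dists = []
    n_excluded = 0
    for chrom, pos in a:
        arr = b_by_chrom.get(chrom)
        if arr is None:
            n_excluded += 1
            continue
        i = np.searchsorted(arr, pos)
        best = min(
            abs(pos - arr[j]) for j in (i - 1, i) if 0 <= j < len(arr)
        )
        dists.append(best)
    if n_excluded:
        log.info("mean_nearest_distance: %d A-sites on chromosomes without B sites",
                 n_excluded)
    return float(np.mean(dists)) if dists else float("nan")


def resample_sites(universe: list[Site], k: int,
                   rng: np.random.Generator) -> set[Site]:
    """Uniform sample of k distinct sites from the universe."""
    if k > len(universe):
        raise ValueError(f"cannot sample {k} sites from universe of {len(universe)}")
    idx = rng.choice(len(universe), size=k, replace=False)
    return {universe[i] for i in idx}


STATISTICS = {
    "num_overlaps": (num_overlaps, "upper"),
    "mean_nearest_distance": (mean_nearest_distance, "lower"),
}


def permutation_test(
    a: set[Site],
    b: set[Site],
    universe: list[Site] | set[Site],
    statistic: str = "num_overlaps",
    n_perm: int = 10_000,
    seed: int = 0,
    randomize_both: bool = False,
) -> PermutationResult:
    """Monte-Carlo test of the observed statistic against resampled A sets.

    ``randomize_both=True`` additionally resamples B each round (an
    alternative reading of two-set randomization); the default resamples
    only A, the conventional randomization-strategy semantics.
    """
    universe_list = sorted(universe)
    universe_set = set(universe_list)
    if not a <= universe_set:
        raise ValueError("A is not a subset of the universe")
    if not b <= universe_set:
        raise ValueError("B is not a subset of the universe")
    func, tail = STATISTICS[statistic]
    observed = func(a, b)
    rng = np.random.default_rng(seed)
    null = np.empty(n_perm)
    for i in range(n_perm):
        a_rand = resample_sites(universe_list, len(a), rng)
        b_rand = resample_sites(universe_list, len(b), rng) if randomize_both else b
        null[i] = func(a_rand, b_rand)
    if tail == "upper":
        extreme = int((null >= observed).sum())
    else:
        extreme = int((null <= observed).sum())
    p = (1 + extreme) / (1 + n_perm)
    return PermutationResult(
        statistic=statistic,
        observed=float(observed),
        null=null,
        p_value=p,
        tail=tail,
        n_perm=n_perm,
        seed=seed,
    )
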