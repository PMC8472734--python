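"""False-discovery-rate q-values.

Two estimators are provided: Benjamini-Hochberg (``pi0 = 1``) and the
Storey estimator, where ``pi0`` — the proportion of true nulls — is
estimated on the lambda grid 0.05, 0.10, ..., 0.95 and extrapolated to
``lambda -> 1`` with a cubic smoother.  In both cases

    q_i = pi0 * min_{j : p_j >= p_i} (m * p_j / rank_j)

clipped to [0, 1]; q is therefore monotone non-decreasing in p.
"""

from __future__ import annotations

import numpy as np
from scipy.interpolate import UnivariateSpline

LAMBDA_GRID = np.arange(0.05, 0.96, 0.05)


def estimate_pi0(pvalues: np.ndarray, lambdas: np.ndarray = LAMBDA_GRID) -> float:
    """Storey's smoother pi0: fit a cubic smoothing spline to pi0(lambda)
    and read it off at the largest lambda, clipped to (0, 1]."""
    p = np.asarray(pvalues, dtype=float)
    m = p.size
    pi0_lambda = np.array([(p > lam).sum() / (m * (1.0 - lam)) for lam in lambdas])
    # smoothing parameter chosen to mimic a low-df smoother (qvalue-style df=3)
    spline = UnivariateSpline(lambdas, pi0_lambda, k=3)
    pi0 = float(spline(lambdas[-1]))
    return float(np.clip(pi0, 1.0 / m if m else 0.0, 1.0))


def compute_qvalues(pvalues: np.ndarray, method: str = "storey") -> np.ndarray:
    """q-values for a p-value vector (no missing values allowed).

    Parameters
    ----------
    method : 'storey' or 'bh'
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value vector")
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1] with no NaN")
    if method == "bh":
        pi0 = 1.0
    elif method == "storey":
        pi0 = estimate_pi0(p)
    else:
        raise ValueError(f"unknown q-value method {method!r}")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order]
    raw = pi0 * m * ranked / np.arange(1, m + 1)
    # enforce monotonicity from the right (step-up)
    qmin = np.minimum.accumulate(raw[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.clip(qmin, 0.0, 1.0)
    return q


def p_threshold_for_q(pvalues: np.ndarray, q_target: float = 0.01,
                      method: str = "bh") -> float:
    """Largest p whose q-value is below ``q_target`` (0.0 if none).

    Diagnostic used to convert an FDR level back to a fixed p-value
    threshold over an analysis universe (e.g. a genome-wide significance
    cut roughly equivalent to FDR 0.01).
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value vector")
    q = compute_qvalues(p, method=method)
    passing = p[q < q_target]
    return float(passing.max()) if passing.size else 0.0
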