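"""Multiple-testing adjustment and rejection-ratio alpha selection.

``bh_adjust`` and ``bonferroni_adjust`` take an explicit family size ``m`` so
a subset of a larger tested family can be adjusted correctly (m defaults to
the vector length). ``alpha_scan`` implements the observed/expected
rejection-ratio calibration: over a grid of test sizes alpha in (0, 0.1],
count observed rejections #{p_i <= alpha}, compare with the alpha * m
expected under the global null, and select the alpha maximizing the
enrichment ratio (ties broken toward the smallest, most conservative alpha).
A ratio of ~1 across the grid means the observed significant tests match the
null expectation; a maximum well above 1 marks a test size at which real
signal is enriched.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["bh_adjust", "bonferroni_adjust", "alpha_scan", "AlphaScanResult"]


def _check_p(p: np.ndarray) -> np.ndarray:
    p = np.asarray(p, dtype=float)
    if p.ndim != 1:
        raise ValueError("p must be a 1-D vector")
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    return p


def _check_m(p: np.ndarray, m: int | None) -> int:
    if m is None:
        return len(p)
    if m < len(p):
        raise ValueError(f"family size m={m} smaller than len(p)={len(p)}")
    return int(m)


def bh_adjust(p, m: int | None = None) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order.

    q_(i) = min_{j >= i} min(1, m * p_(j) / j) over the ascending order
    statistics. With m > len(p) the supplied values are treated as a subset
    of an m-test family (the unsupplied tests cannot lower any adjusted
    value, so occupying ranks 1..len(p) is the conservative completion).
    """
    p = _check_p(p)
    m = _check_m(p, m)
    if len(p) == 0:
        return p.copy()
    order = np.argsort(p, kind="mergesort")
    ranks = np.arange(1, len(p) + 1)
    stepup = np.minimum.accumulate((m * p[order] / ranks)[::-1])[::-1]
    q = np.empty_like(p)
    q[order] = np.minimum(stepup, 1.0)
    return q


def bonferroni_adjust(p, m: int | None = None) -> np.ndarray:
    """Bonferroni adjustment: min(1, m * p) elementwise."""
    p = _check_p(p)
    m = _check_m(p, m)
    return np.minimum(1.0, m * p)


@dataclass
class AlphaScanResult:
    """Observed vs expected rejections over an alpha grid."""

    grid: np.ndarray        # alpha values, ascending, in (0, 0.1]
    observed: np.ndarray    # int rejections at each alpha
    expected: np.ndarray    # alpha * m
    ratio: np.ndarray       # observed / expected
    alpha_star: float | None  # None when no p-value falls in the grid range
    m: int


def alpha_scan(p, step: float = 0.001, alpha_max: float = 0.1) -> AlphaScanResult:
    """Scan test sizes alpha = step, 2*step, ..., alpha_max.

    observed(alpha) = #{p_i <= alpha}, expected(alpha) = alpha * m with
    m = len(p); alpha_star is the smallest alpha attaining the maximal
    observed/expected ratio, or None (flagged) when nothing is rejected at
    any grid alpha. alpha = 0 is excluded since its expectation is zero.
    """
    p = _check_p(p)
    if len(p) == 0:
        raise ValueError("alpha_scan needs a non-empty p-value vector")
    if not (0 < step <= alpha_max):
        raise ValueError("need 0 < step <= alpha_max")
    m = len(p)
    n_steps = int(round(alpha_max / step))
    grid = step * np.arange(1, n_steps + 1)
    observed = np.array([(p <= a + 1e-12).sum() for a in grid])
    expected = grid * m
    ratio = observed / expected
    if observed[-1] == 0:
        alpha_star = None
    else:
        alpha_star = float(grid[int(np.argmax(ratio))])  # argmax -> first max
    return AlphaScanResult(grid, observed, expected, ratio, alpha_star, m)
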