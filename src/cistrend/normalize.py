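"""Median-of-ratios count normalization.

The size factor of sample j is the median, over genes with strictly positive
counts in every sample, of counts(i, j) / geomean_i, where geomean_i is the
geometric mean of gene i across samples. Normalized expression is the raw
count divided by its sample's size factor; no log or variance-stabilizing
transform is applied (the downstream trend test is rank-based, and the linear
test runs on the normalized scale unless the caller pre-logs).
"""

from __future__ import annotations

import numpy as np

from ._types import CountMatrix, NormalizedExpression, SizeFactors

__all__ = ["size_factors", "normalize"]


def size_factors(counts: CountMatrix) -> SizeFactors:
    """Median-of-ratios size factors.

    Only genes with all-positive counts enter the median; if no gene
    qualifies the estimator is undefined and a ValueError is raised.
    """
    c = counts.counts.astype(float)
    qualifying = (c > 0).all(axis=1)
    if not qualifying.any():
        raise ValueError(
            "normalization impossible: no gene has strictly positive counts "
            "in every sample"
        )
    cq = c[qualifying, :]
    log_geomean = np.mean(np.log(cq), axis=1, keepdims=True)
    ratios = np.exp(np.log(cq) - log_geomean)  # counts / geometric mean
    s = np.median(ratios, axis=0)
    return SizeFactors(list(counts.samples), s)


def normalize(counts: CountMatrix, s: SizeFactors) -> NormalizedExpression:
    """Divide each sample's counts by its size factor (element-wise)."""
    if list(s.samples) != list(counts.samples):
        raise ValueError(
            "size factors were computed for a different sample set/order"
        )
    values = counts.counts / s.factors[np.newaxis, :]
    return NormalizedExpression(
        list(counts.genes), list(counts.samples), values, s
    )
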