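"""Normalization: quantile normalization, median-of-ratios size factors, log2.

Both schemes are implemented from their defining formulas rather than by
calling external packages, so they can be verified against closed-form
cases and library cross-checks independently.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .expression_io import PLATFORM_CONTINUOUS, PLATFORM_COUNTS, ExpressionMatrix

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SizeFactors:
    """Per-sample positive scale factors (median-of-ratios estimator)."""

    factors: pd.Series

    def __post_init__(self) -> None:
        if (self.factors <= 0).any() or not np.isfinite(self.factors).all():
            raise ValueError("size factors must be positive and finite")


def quantile_normalize(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Force every sample onto the common (mean) empirical distribution.

    The value at rank r in each sample becomes the across-sample mean of
    rank-r values; ties within a sample receive the mean of the reference
    values spanning their tied ranks.
    """
    if matrix.platform != PLATFORM_CONTINUOUS:
        raise ValueError("quantile normalization requires the continuous platform")
    X = matrix.values.to_numpy(dtype=float)
    n_genes, n_samples = X.shape
    if n_samples < 2:
        raise ValueError("quantile normalization needs at least 2 samples")
    reference = np.sort(X, axis=0).mean(axis=1)
    out = np.empty_like(X)
    for j in range(n_samples):
        col = X[:, j]
        order = np.argsort(col, kind="stable")
        assigned = np.empty(n_genes)
        assigned[order] = reference
        # ties: every occurrence of an equal value gets the mean of the
        # reference values its tied span covers
        uniq, inverse = np.unique(col, return_inverse=True)
        sums = np.bincount(inverse, weights=assigned, minlength=uniq.size)
        counts = np.bincount(inverse, minlength=uniq.size)
        out[:, j] = (sums / counts)[inverse]
    values = pd.DataFrame(out, index=matrix.values.index, columns=matrix.values.columns)
    return replace(matrix, values=values, normalized=True)


def size_factors(
    matrix: ExpressionMatrix,
    pseudocount: float = 0.0,
    unit_geomean: bool = False,
) -> SizeFactors:
    """Median-of-ratios depth factors for a count matrix.

    For sample j: median over genes (restricted to genes with a positive
    geometric mean) of count[g, j] / geomean_over_samples(count[g, .]).
    ``unit_geomean`` rescales the factors to geometric mean 1 — a
    convention flag that cannot change downstream z-scores.
    """
    if matrix.platform != PLATFORM_COUNTS:
        raise ValueError("size factors require the counts platform")
    X = matrix.values.to_numpy(dtype=float) + pseudocount
    all_positive = (X > 0).all(axis=1)
    if not all_positive.any():
        raise ValueError(
            "no gene has positive counts in every sample; consider the "
            "pseudocount option"
        )
    logX = np.log(X[all_positive, :])
    log_geomean = logX.mean(axis=1)
    log_factors = np.median(logX - log_geomean[:, None], axis=0)
    if unit_geomean:
        log_factors = log_factors - log_factors.mean()
    return SizeFactors(factors=pd.Series(np.exp(log_factors), index=matrix.values.columns))


def apply_size_factors(matrix: ExpressionMatrix, factors: SizeFactors) -> ExpressionMatrix:
    """Divide each sample by its size factor; output is depth-normalized."""
    missing = set(matrix.samples) - set(factors.factors.index)
    if missing:
        raise ValueError(f"size factors missing for samples: {sorted(missing)}")
    f = factors.factors.reindex(matrix.values.columns)
    values = matrix.values / f
    return ExpressionMatrix(values=values, platform=PLATFORM_CONTINUOUS, normalized=True)


def log2_transform(matrix: ExpressionMatrix, pseudocount: float = 1.0) -> ExpressionMatrix:
    """Elementwise log2(value + pseudocount)."""
    if pseudocount < 0:
        raise ValueError("pseudocount must be non-negative")
    shifted = matrix.values + pseudocount
    if (shifted.to_numpy() <= 0).any():
        raise ValueError(
            "log2 of non-positive value; add a pseudocount (e.g. 1) to shift "
            "zeros off the log singularity"
        )
    return ExpressionMatrix(
        values=np.log2(shifted), platform=PLATFORM_CONTINUOUS, normalized=matrix.normalized
    )
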