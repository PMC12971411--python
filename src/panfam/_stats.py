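"""Shared statistical kernels.

A single Pearson-correlation kernel backs both the SV-expression
association test and the gene-count/expression-dosage test, so the two
stages are numerically identical on identical input.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
from scipy import stats


@dataclass(frozen=True)
class CorrelationResult:
    r: float
    p: float
    n: int
    reason: str | None = None  # set (with r/p = nan) when undefined

    @property
    def defined(self) -> bool:
        return self.reason is None


def pearson(x, y) -> CorrelationResult:
    """Pearson r with a two-sided p from the t distribution (n-2 df).

    Constant input or n < 3 yields an undefined result carrying a reason
    code instead of raising.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError(f"length mismatch: {x.shape} vs {y.shape}")
    n = x.size
    if n < 3:
        return CorrelationResult(math.nan, math.nan, n, reason="n_too_small")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return CorrelationResult(math.nan, math.nan, n, reason="constant_input")
    r, p = stats.pearsonr(x, y)
    return CorrelationResult(float(r), float(p), n)


def percent(count: float, total: float, decimals: int = 1) -> float:
    """Percentage rounded half-up to `decimals` (matching printed tables)."""
    if total == 0:
        raise ZeroDivisionError("percent of an empty total")
    q = Decimal(1).scaleb(-decimals)
    return float(
        (Decimal(count) / Decimal(total) * 100).quantize(q, rounding=ROUND_HALF_UP)
    )
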