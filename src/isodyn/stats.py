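"""Shared statistical primitives: exact 2x2 tests and FDR control.

Two-sided conventions, chosen once and used everywhere:

* Fisher's exact test sums hypergeometric probabilities of all tables (with
  the observed margins) whose probability is at most that of the observed
  table, with a 1e-7 relative tolerance on the comparison.
* The rate test conditions on the total count: k1 ~ Binomial(k1 + k2,
  s1 / (s1 + s2)) under the null that both conditions share one rate, with
  the two-sided p-value given by tail doubling capped at 1.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import List, Sequence

import numpy as np
from scipy import stats as sps

from .models import DataError


@dataclass(frozen=True)
class CountTestResult:
    log2_fold_change: float
    p_value: float
    adjusted_p: float


def fisher_exact_2x2(table) -> float:
    """Two-sided Fisher exact p-value for a 2x2 table of non-negative counts."""
    arr = np.asarray(table, dtype=np.int64)
    if arr.shape != (2, 2):
        raise DataError(f"expected a 2x2 table, got shape {arr.shape}")
    if np.any(arr < 0):
        raise DataError("negative entry in 2x2 table")
    if arr.sum() == 0:
        raise DataError("all-zero 2x2 table")
    p = float(min(sps.fisher_exact(arr, alternative="two-sided").pvalue, 1.0))
    return p if p > 0.0 else float(np.nextafter(0, 1))


def binomial_rate_test(k1: int, k2: int, s1: float, s2: float) -> float:
    """Exact conditioned test of equal rates for counts k1, k2 with size factors s1, s2.

    Under the null, k1 ~ Binomial(k1 + k2, s1/(s1 + s2)); two-sided p is
    min(1, 2 * min(lower tail, upper tail)).
    """
    if k1 < 0 or k2 < 0:
        raise DataError("counts must be non-negative")
    if s1 <= 0 or s2 <= 0:
        raise DataError("size factors must be positive")
    n = k1 + k2
    if n == 0:
        raise DataError("k1 + k2 must be >= 1")
    p0 = s1 / (s1 + s2)
    lower = float(sps.binom.cdf(k1, n, p0))
    upper = float(sps.binom.sf(k1 - 1, n, p0))
    return min(1.0, 2.0 * min(lower, upper))


def bh_adjust(p_values: Sequence[float]) -> List[float]:
    """Benjamini-Hochberg step-up adjusted p-values, input order preserved."""
    ps = np.asarray(list(p_values), dtype=np.float64)
    if ps.size == 0:
        return []
    if np.any(np.isnan(ps)) or np.any(ps < 0) or np.any(ps > 1):
        raise DataError("p-values must lie in [0, 1]")
    return [float(v) for v in sps.false_discovery_control(ps, method="bh")]


def log2_fold_change(k1: float, k2: float, s1: float, s2: float,
                     pseudocount: float = 0.5) -> float:
    """log2 ratio of size-factor-normalized counts, stabilized by a pseudocount."""
    if s1 <= 0 or s2 <= 0:
        raise DataError("size factors must be positive")
    if k1 < 0 or k2 < 0:
        raise DataError("counts must be non-negative")
    return math.log2((k1 / s1 + pseudocount) / (k2 / s2 + pseudocount))
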