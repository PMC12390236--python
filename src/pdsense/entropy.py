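"""Approximate and sample entropy of short physiological time series.

Both statistics quantify the (ir)regularity of a signal by counting
template matches under the Chebyshev distance: approximate entropy
(Pincus) compares the log template-match densities at embedding dimensions
m and m+1 including self-matches; sample entropy (Richman & Moorman)
excludes self-matches and reports -ln(A/B) where B and A count matching
template pairs of length m and m+1. Conventional parameters m = 2 and
r = 0.2 x sd are used throughout.

The O(n^2) pair scan is JIT-compiled with numba; a single pass produces
the counts for both statistics.
"""

from __future__ import annotations

import numpy as np
from numba import njit

EMBEDDING_M = 2
TOLERANCE_FACTOR = 0.2


@njit(cache=True)
def _pair_counts(x: np.ndarray, m: int, r: float):
    """Template-match counts for ApEn and SampEn in one pair scan.

    Returns (cm, cm1, B, A): per-template match counts (self included) at
    lengths m and m+1 for ApEn, and total matched pairs at lengths m and
    m+1 (self excluded, templates restricted to the first n-m) for SampEn.
    """
    n = x.shape[0]
    nm = n - m + 1     # number of m-templates
    nm1 = n - m        # number of (m+1)-templates
    cm = np.ones(nm)
    cm1 = np.ones(nm1)
    B = 0.0
    A = 0.0
    for i in range(nm):
        for j in range(i + 1, nm):
            d = 0.0
            for k in range(m):
                diff = abs(x[i + k] - x[j + k])
                if diff > d:
                    d = diff
            if d <= r:
                cm[i] += 1.0
                cm[j] += 1.0
                if j < nm1:  # both windows extendable (i < j < nm1)
                    B += 1.0
                    d1 = abs(x[i + m] - x[j + m])
                    if d1 > d:
                        d = d1
                    if d <= r:
                        cm1[i] += 1.0
                        cm1[j] += 1.0
                        A += 1.0
    return cm, cm1, B, A


def approximate_and_sample_entropy(
    x: np.ndarray, m: int = EMBEDDING_M, r: float | None = None
) -> tuple:
    """Return (ApEn, SampEn) of a 1-D sequence.

    ``r`` defaults to 0.2 x sd(x). Degenerate inputs (constant signal, or
    too short to embed) yield (0.0, 0.0); an unmatched SampEn numerator
    (A = 0 or B = 0) also yields 0 so feature tables stay finite.
    """
    x = np.ascontiguousarray(x, dtype=np.float64)
    if x.size < m + 2:
        return 0.0, 0.0
    sd = float(np.std(x))
    if r is None:
        r = TOLERANCE_FACTOR * sd
    if sd == 0.0 or r <= 0.0:
        return 0.0, 0.0
    cm, cm1, B, A = _pair_counts(x, m, float(r))
    nm = x.size - m + 1
    nm1 = x.size - m
    phi_m = float(np.mean(np.log(cm / nm)))
    phi_m1 = float(np.mean(np.log(cm1 / nm1)))
    apen = phi_m - phi_m1
    sampen = -np.log(A / B) if A > 0 and B > 0 else 0.0
    return apen, float(sampen)


def approximate_entropy(x, m: int = EMBEDDING_M, r: float | None = None) -> float:
    return approximate_and_sample_entropy(x, m, r)[0]


def sample_entropy(x, m: int = EMBEDDING_M, r: float | None = None) -> float:
    return approximate_and_sample_entropy(x, m, r)[1]
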