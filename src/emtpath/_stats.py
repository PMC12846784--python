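"""Shared moment statistics with fixed degenerate-case conventions.

All edge-length and aggregation statistics in the pathomics pipeline use
population (biased) moments: variance divides by n, skewness is
``m3 / m2**1.5`` and kurtosis is the Fisher excess ``m4 / m2**2 - 3``.
When the second central moment is zero (constant input, or a single
value) skewness and kurtosis are defined as 0 rather than NaN so that
degenerate patches still produce dense feature vectors.
"""

from __future__ import annotations

import numpy as np

STAT_NAMES = ("min", "max", "mean", "variance", "skewness", "kurtosis")


def six_stats(values) -> np.ndarray:
    """Return (min, max, mean, variance, skewness, kurtosis) of *values*.

    Empty input yields six NaNs (the missing-value convention of the
    feature pipeline).  A constant sample yields zero variance, skewness
    and kurtosis.
    """
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        return np.full(6, np.nan)
    m = v.mean()
    d = v - m
    m2 = np.mean(d**2)
    if m2 <= 0.0:
        skew = kurt = 0.0
        m2 = max(m2, 0.0)
    else:
        skew = np.mean(d**3) / m2**1.5
        kurt = np.mean(d**4) / m2**2 - 3.0
    return np.array([v.min(), v.max(), m, m2, skew, kurt])
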