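"""Independent reference implementations used only as test oracles."""

from __future__ import annotations

import math

import numpy as np


def sampen_bruteforce_counts(x, m: int, r: float) -> tuple[int, int]:
    """Brute-force template-pair counts for sample entropy.

    Enumerates every pair (i, j), i < j, of the N-m templates that have a
    length-(m+1) extension and compares their Chebyshev distances to r
    directly — first over the m leading coordinates (B), then including
    coordinate m (A).  Kept deliberately simple and separate from the
    package implementation.
    """
    x = np.asarray(x, dtype=np.float64)
    n = x.size - m
    a = b = 0
    for i in range(n - 1):
        nj = n - i - 1  # candidates j = i+1 .. n-1
        d = np.zeros(nj)
        for k in range(m):
            np.maximum(d, np.abs(x[i + k] - x[i + 1 + k : i + 1 + k + nj]), out=d)
        within = d <= r
        b += int(within.sum())
        np.maximum(d, np.abs(x[i + m] - x[i + 1 + m : i + 1 + m + nj]), out=d)
        a += int((d <= r).sum())
    return a, b


def sampen_bruteforce(x, m: int, r: float) -> float:
    a, b = sampen_bruteforce_counts(x, m, r)
    if a == 0 or b == 0:
        return math.inf
    return -math.log(a / b)
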