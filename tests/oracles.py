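"""Independent brute-force oracles used only by the tests.

These deliberately mirror the textbook definitions with literal nested
loops and no shared code with the package implementation.
"""

from __future__ import annotations

import math

import numpy as np


def apen_bruteforce(x, m: int, r_frac: float) -> float:
    """Literal O(N^2) approximate entropy: Chebyshev distance, self-matches
    included, natural log, r = r_frac * population SD."""
    x = [float(v) for v in np.asarray(x).ravel()]
    n = len(x)
    mean = sum(x) / n
    sd = math.sqrt(sum((v - mean) ** 2 for v in x) / n)
    r = r_frac * sd

    def phi(mm: int) -> float:
        count_templates = n - mm + 1
        total = 0.0
        for i in range(count_templates):
            c = 0
            for j in range(count_templates):
                within = True
                for k in range(mm):
                    if abs(x[i + k] - x[j + k]) > r:
                        within = False
                        break
                if within:
                    c += 1
            total += math.log(c / count_templates)
        return total / count_templates

    return phi(m) - phi(m + 1)


def shannon_entropy_bruteforce(x, bin_width: float) -> float:
    """Histogram anchored at the minimum; -sum p log2 p over occupied bins."""
    x = [float(v) for v in np.asarray(x).ravel()]
    lo = min(x)
    counts: dict[int, int] = {}
    for v in x:
        k = int((v - lo) // bin_width)
        counts[k] = counts.get(k, 0) + 1
    n = len(x)
    return -sum((c / n) * math.log2(c / n) for c in counts.values())
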