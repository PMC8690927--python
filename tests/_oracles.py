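"""Independent brute-force oracles used to cross-check the implementation.

These deliberately avoid the code paths they validate: Fisher p-values come
from direct hypergeometric enumeration with ``math.comb``, and BH q-values
from the quadratic-time step-up definition.
"""

from math import comb

import numpy as np


def fisher_p_enumeration(n11: int, n10: int, n01: int, n00: int) -> float:
    """Two-sided Fisher p by exhaustive enumeration over tables with fixed margins."""
    r1, r2 = n11 + n10, n01 + n00
    c1 = n11 + n01
    n = r1 + r2
    denom = comb(n, c1)
    lo, hi = max(0, c1 - r2), min(r1, c1)
    pmf = {k: comb(r1, k) * comb(r2, c1 - k) / denom for k in range(lo, hi + 1)}
    observed = pmf[n11]
    # standard epsilon guard against floating ties at the observed probability
    return min(1.0, sum(p for p in pmf.values() if p <= observed * (1 + 1e-7)))


def bh_step_up(p_values) -> np.ndarray:
    """Benjamini-Hochberg q-values by the literal definition q_(i) = min_{j>=i} p_(j) m / j."""
    p = np.asarray(p_values, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    sorted_p = p[order]
    q_sorted = [
        min(1.0, min(sorted_p[j] * m / (j + 1) for j in range(i, m)))
        for i in range(m)
    ]
    out = np.empty(m)
    out[order] = q_sorted
    return out
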