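"""Independent reference implementations used as test oracles.

These deliberately avoid the code paths (and, where feasible, the libraries)
they are used to check.
"""

import math

import numpy as np


def poisson_sf_oracle(k: int, lam: float) -> float:
    """P(X >= k) by direct pmf summation (log-space terms, fsum), scipy-free."""
    if k <= 0:
        return 1.0
    if lam == 0:
        return 0.0
    n_max = int(max(k, lam) + 60 * math.sqrt(lam) + 200)
    log_lam = math.log(lam)
    terms = [
        math.exp(-lam + i * log_lam - math.lgamma(i + 1)) for i in range(k, n_max + 1)
    ]
    return math.fsum(terms)


def bh_oracle(p: np.ndarray) -> np.ndarray:
    """Textbook BH step-up, quadratic min-over-larger-ranks form."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    q = np.empty(m)
    for rank_i in range(m):
        q[order[rank_i]] = min(
            min(p[order[j]] * m / (j + 1) for j in range(rank_i, m)), 1.0
        )
    return q
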