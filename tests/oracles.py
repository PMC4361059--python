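"""Independent brute-force oracles used to check the statistical routines.

These deliberately avoid the code paths they verify: the Fisher oracle
enumerates hypergeometric tables with exact integer arithmetic, and the
rank-sum oracle is a Monte-Carlo permutation test.
"""

from math import comb

import numpy as np


def fisher_oracle(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher p by full hypergeometric enumeration.

    Fixes the observed margins, enumerates every table, and sums the
    probabilities of tables no more probable than the observed one.
    Integer weights make the tie comparison exact.
    """
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2
    if r1 == 0 or r2 == 0 or c1 == 0 or c1 == n:
        return 1.0
    xs = range(max(0, c1 - r2), min(r1, c1) + 1)
    weights = {x: comb(r1, x) * comb(r2, c1 - x) for x in xs}
    obs = weights[a]
    return sum(w for w in weights.values() if w <= obs) / sum(weights.values())


def ranksum_less_oracle(x, y, n_perm: int = 4000, seed: int = 0) -> float:
    """One-sided permutation p for mean(x) < mean(y) via rank sums."""
    rng = np.random.default_rng(seed)
    pooled = np.concatenate([x, y])
    ranks = np.argsort(np.argsort(pooled, kind="stable"), kind="stable")
    nx = len(x)
    obs = ranks[:nx].sum()
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(len(pooled))
        if ranks[perm[:nx]].sum() <= obs:
            count += 1
    return (count + 1) / (n_perm + 1)


def binom_tail_oracle(n: int, p: float, k: int) -> float:
    """P(X >= k) for X ~ Binomial(n, p), by direct summation."""
    total = 0.0
    for x in range(k, n + 1):
        total += comb(n, x) * p**x * (1 - p) ** (n - x)
    return total
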