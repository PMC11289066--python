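"""Independent reference computations used only by the test suite.

These deliberately take different numerical routes from the package:
fixed-order Gauss-Legendre quadrature on a compactified domain for the
Bayes factor, explicit combinatorial sums for binomial tails, and direct
textbook formulas for t statistics.
"""

import math

import numpy as np
from scipy import stats as sps


def jzs_bf_oracle(t: float, n: int, scale: float = 0.707, alternative: str = "two_sided") -> float:
    """JZS BF10 by dense Gauss-Legendre after delta = scale * tan(theta).

    The Cauchy prior becomes uniform in theta over (-pi/2, pi/2), so the
    marginal likelihood is the plain average of the noncentral-t density
    over the theta grid (doubled and restricted to one side for the
    half-Cauchy variants).
    """
    df = n - 1
    if alternative == "two_sided":
        lo, hi, mult = -math.pi / 2, math.pi / 2, 1.0
    elif alternative == "greater":
        lo, hi, mult = 0.0, math.pi / 2, 2.0
    elif alternative == "less":
        lo, hi, mult = -math.pi / 2, 0.0, 2.0
    else:
        raise ValueError(alternative)
    nodes, weights = np.polynomial.legendre.leggauss(4000)
    theta = 0.5 * (hi - lo) * nodes + 0.5 * (hi + lo)
    w = 0.5 * (hi - lo) * weights
    delta = scale * np.tan(theta)
    like = sps.nct.pdf(t, df, delta * math.sqrt(n))
    marginal = mult * float(np.sum(w * like)) / math.pi
    return marginal / float(sps.t.pdf(t, df))


def binom_upper_tail_brute(k: int, n: int, p0: float) -> float:
    """P(X >= k) by direct summation of binomial point masses."""
    total = 0.0
    for i in range(k, n + 1):
        total += math.comb(n, i) * p0**i * (1 - p0) ** (n - i)
    return min(total, 1.0)


def t_stat_textbook(values, mu0: float) -> tuple[float, int]:
    """t = (xbar - mu0) / (s / sqrt(n)) computed from first principles."""
    values = list(map(float, values))
    n = len(values)
    xbar = sum(values) / n
    s2 = sum((v - xbar) ** 2 for v in values) / (n - 1)
    t = (xbar - mu0) / math.sqrt(s2 / n)
    return t, n - 1


def pearson_r_hand(x, y) -> float:
    x = list(map(float, x))
    y = list(map(float, y))
    n = len(x)
    mx, my = sum(x) / n, sum(y) / n
    num = sum((a - mx) * (b - my) for a, b in zip(x, y))
    den = math.sqrt(sum((a - mx) ** 2 for a in x) * sum((b - my) ** 2 for b in y))
    return num / den


def exact_binom_power_brute(g: float, alpha: float, power: float, p0: float = 0.5) -> int:
    """Smallest n whose exact one-sided test reaches the target power,
    scanning k directly (no isf shortcuts)."""
    p1 = p0 + g
    for n in range(1, 1000):
        k_crit = None
        for k in range(n + 1):
            if binom_upper_tail_brute(k, n, p0) <= alpha:
                k_crit = k
                break
        if k_crit is None:
            continue
        if binom_upper_tail_brute(k_crit, n, p1) >= power:
            return n
    raise RuntimeError("not found")
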