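"""Inferential layer: one-sided t-tests, effect sizes, JZS Bayes factors,
exact binomial tests, a priori power solvers, and sequential stopping.

Conventions
-----------
* Effect size for a one-sample test is Cohen's d = (mean - mu0) / SD, with a
  one-sided 95% confidence interval reported as ``[lower; +inf)`` obtained by
  inverting the noncentral-t distribution.
* The default Bayes factor places a Cauchy prior with scale ``r = 0.707`` on
  the standardized effect delta; one-sided variants restrict the prior to a
  half-Cauchy on the side of the alternative.  BF10 is the ratio of the
  marginal likelihood of the observed t statistic under that prior to its
  likelihood under the point null, i.e.

      BF10 = [ integral of T_df(t; ncp = delta*sqrt(n)) * pi(delta) ddelta ]
             / T_df(t; ncp = 0)

  where ``T_df(.; ncp)`` is the noncentral-t density.  The integral is
  evaluated by adaptive quadrature over the infinite domain.
* p-values are kept at full floating precision; rounding is a display
  concern.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import integrate, optimize
from scipy import stats as sps

__all__ = [
    "StatResult",
    "PowerSpec",
    "StoppingRule",
    "SequentialDecision",
    "one_sample_t",
    "paired_t",
    "cohens_d_ci_lower",
    "jzs_bf",
    "binomial_test_one_sided",
    "power_t_one_sample",
    "power_binomial_one_sided",
    "sequential_bf_stop",
    "pearson_r",
    "bonferroni",
]

_ALTERNATIVES = ("greater", "less", "two_sided")


def _norm_alternative(alternative: str) -> str:
    alt = alternative.replace("-", "_").lower()
    if alt == "two_sided" or alt == "twosided":
        alt = "two_sided"
    if alt not in _ALTERNATIVES:
        raise ValueError(f"alternative must be one of {_ALTERNATIVES}, got {alternative!r}")
    return alt


@dataclass
class StatResult:
    """Result of a one-sample or paired t-test with Bayesian companion.

    ``d_ci_lower`` is the lower bound of the one-sided 95% CI on Cohen's d
    (the upper bound is +inf).  ``bf10`` is ``None`` when the Bayes factor
    was not requested.
    """

    t: float
    df: int
    p: float
    d: float
    d_ci_lower: float
    n: int
    alternative: str
    mean: float
    sd: float
    mu0: float
    bf10: Optional[float] = None

    def as_dict(self) -> dict:
        return {
            "t": self.t,
            "df": self.df,
            "p": self.p,
            "d": self.d,
            "d_ci_lower": self.d_ci_lower,
            "bf10": self.bf10,
            "n": self.n,
            "alternative": self.alternative,
            "mean": self.mean,
            "sd": self.sd,
            "mu0": self.mu0,
        }


@dataclass
class PowerSpec:
    """An a priori power analysis: inputs and the solved minimal n."""

    test: str
    effect: float
    alpha: float
    power: float
    n_min: int
    method: str = "exact"


@dataclass
class StoppingRule:
    """Sequential Bayesian sampling plan with symmetric evidence thresholds."""

    bf_upper: float = 5.0
    bf_lower: float = 1.0 / 5.0
    batch_sizes: Sequence[int] = (50, 25)
    n_max: int = 150

    def __post_init__(self) -> None:
        if not (self.bf_lower < 1.0 < self.bf_upper):
            raise ValueError("need bf_lower < 1 < bf_upper")
        if any(b <= 0 for b in self.batch_sizes):
            raise ValueError("batch sizes must be positive")

    def batch_size(self, i: int) -> int:
        """Size of the i-th batch (0-based); the last listed size repeats."""
        if i < len(self.batch_sizes):
            return int(self.batch_sizes[i])
        return int(self.batch_sizes[-1])


@dataclass
class SequentialDecision:
    decision: str  # stop_h1 | stop_h0 | continue | cap_reached
    n_used: int
    n_batches: int
    bf_final: Optional[float] = None


def _t_core(values: np.ndarray, mu0: float, alternative: str) -> tuple:
    n = values.size
    if n < 2:
        raise ValueError("need at least two observations")
    mean = float(values.mean())
    sd = float(values.std(ddof=1))
    eps = 1e-12 * max(1.0, abs(mean))
    if sd <= eps:
        if abs(mean - mu0) <= eps:
            # all observations at mu0: no evidence either way
            return 0.0, n - 1, mean, 0.0
        raise ValueError("degenerate sample: zero variance")
    t = (mean - mu0) / (sd / math.sqrt(n))
    return t, n - 1, mean, sd


def _t_pvalue(t: float, df: int, alternative: str) -> float:
    if alternative == "greater":
        return float(sps.t.sf(t, df))
    if alternative == "less":
        return float(sps.t.cdf(t, df))
    return float(2.0 * sps.t.sf(abs(t), df))


def one_sample_t(
    values,
    mu0: float = 0.5,
    alternative: str = "greater",
    compute_bf: bool = True,
    rscale: float = 0.707,
    ci_level: float = 0.95,
) -> StatResult:
    """One-sample Student t-test against ``mu0`` with d, one-sided CI and BF10.

    Raises ``ValueError`` on a zero-variance sample whose mean differs from
    ``mu0`` (the statistic is undefined); a sample lying exactly at ``mu0``
    yields t = 0.
    """
    alternative = _norm_alternative(alternative)
    values = np.asarray(values, dtype=float)
    t, df, mean, sd = _t_core(values, mu0, alternative)
    n = df + 1
    p = _t_pvalue(t, df, alternative)
    d = (mean - mu0) / sd if sd > 0 else 0.0
    d_lo = cohens_d_ci_lower(d, n, level=ci_level)
    bf = jzs_bf(t, n, scale=rscale, alternative=alternative) if compute_bf else None
    return StatResult(
        t=t, df=df, p=p, d=d, d_ci_lower=d_lo, n=n,
        alternative=alternative, mean=mean, sd=sd, mu0=mu0, bf10=bf,
    )


def paired_t(
    a,
    b,
    alternative: str = "greater",
    compute_bf: bool = True,
    rscale: float = 0.707,
    ci_level: float = 0.95,
) -> StatResult:
    """Paired t-test on ``a - b``; reduces to :func:`one_sample_t` at mu0=0.

    With ``alternative="greater"`` the alternative hypothesis is
    ``mean(a) > mean(b)``.  Cohen's d is ``mean(diff) / SD(diff)``.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"length mismatch: {a.shape} vs {b.shape}")
    return one_sample_t(
        a - b, mu0=0.0, alternative=alternative,
        compute_bf=compute_bf, rscale=rscale, ci_level=ci_level,
    )


def cohens_d_ci_lower(d: float, n: int, level: float = 0.95) -> float:
    """Lower bound of the one-sided ``level`` CI on a one-sample Cohen's d.

    Solves for the noncentrality parameter ``ncp`` such that the
    noncentral-t CDF evaluated at the observed statistic ``t = d*sqrt(n)``
    equals ``level``; the bound is ``ncp / sqrt(n)``.  The matching upper
    bound is +inf.
    """
    if n < 2:
        raise ValueError("need n >= 2")
    t = d * math.sqrt(n)
    df = n - 1

    def fn(ncp: float) -> float:
        return sps.nct.cdf(t, df, ncp) - level

    lo, hi = t - 2.0, t + 2.0
    while fn(lo) < 0:
        lo -= 2.0
    while fn(hi) > 0:
        hi += 2.0
    ncp = optimize.brentq(fn, lo, hi, xtol=1e-10)
    return ncp / math.sqrt(n)


def _jzs_integrand(delta: np.ndarray, t: float, df: int, n: int, scale: float):
    return sps.nct.pdf(t, df, delta * math.sqrt(n)) * sps.cauchy.pdf(delta, 0.0, scale)


def jzs_bf(
    t: float,
    n: int,
    scale: float = 0.707,
    alternative: str = "two_sided",
    epsrel: float = 1e-9,
) -> float:
    """Default-prior (JZS) Bayes factor BF10 for a one-sample t statistic.

    ``alternative="greater"`` / ``"less"`` use a half-Cauchy prior on the
    corresponding side; ``"two_sided"`` uses the full Cauchy.  Raises
    ``RuntimeError`` if the quadrature does not reach a relative accuracy of
    1e-6.
    """
    alternative = _norm_alternative(alternative)
    if n < 2:
        raise ValueError("need n >= 2")
    if scale <= 0:
        raise ValueError("scale must be positive")
    df = n - 1
    null_like = sps.t.pdf(t, df)

    if alternative == "two_sided":
        num, err = integrate.quad(
            _jzs_integrand, -np.inf, np.inf, args=(t, df, n, scale),
            epsabs=0.0, epsrel=epsrel, limit=200,
        )
    else:
        sign = 1.0 if alternative == "greater" else -1.0

        def half(delta, *a):
            return 2.0 * _jzs_integrand(sign * delta, *a)

        num, err = integrate.quad(
            half, 0.0, np.inf, args=(t, df, n, scale),
            epsabs=0.0, epsrel=epsrel, limit=200,
        )
    if num <= 0 or not np.isfinite(num) or err > 1e-6 * num:
        raise RuntimeError(
            f"Bayes-factor quadrature did not converge (value={num}, abserr={err})"
        )
    return float(num / null_like)


def binomial_test_one_sided(k: int, n: int, p0: float = 0.5) -> float:
    """Exact upper-tail binomial probability P(X >= k | n, p0)."""
    if not (0 <= k <= n):
        raise ValueError("need 0 <= k <= n")
    return float(sps.binom.sf(k - 1, n, p0))


def power_t_one_sample(
    d: float,
    alpha: float = 0.05,
    power: float = 0.90,
    alternative: str = "greater",
    n_max: int = 100_000,
) -> int:
    """Smallest n for a one-sided one-sample t-test to reach ``power``.

    Power at sample size n is ``P(T' > t_crit)`` where ``T'`` follows the
    noncentral t with ``df = n - 1`` and ``ncp = d * sqrt(n)`` and ``t_crit``
    is the upper ``alpha`` quantile of the central t.
    """
    if d <= 0:
        raise ValueError("effect size must be positive")
    _norm_alternative(alternative)
    for n in range(2, n_max + 1):
        df = n - 1
        tcrit = sps.t.isf(alpha, df)
        if sps.nct.sf(tcrit, df, d * math.sqrt(n)) >= power:
            return n
    raise RuntimeError("no n found below n_max")


def _binom_critical_k(n: int, alpha: float, p0: float) -> int:
    """Smallest k with P(X >= k | n, p0) <= alpha for the exact test."""
    k = int(sps.binom.isf(alpha, n, p0)) + 1
    while k <= n and sps.binom.sf(k - 1, n, p0) > alpha:
        k += 1
    while k >= 1 and sps.binom.sf(k - 2, n, p0) <= alpha:
        k -= 1
    return k


def power_binomial_one_sided(
    g: float,
    alpha: float = 0.05,
    power: float = 0.90,
    p0: float = 0.5,
    method: str = "exact",
    n_max: int = 100_000,
) -> int:
    """Smallest n for a one-sided binomial test of p0 against p0 + g.

    ``method="exact"`` uses the exact test: for each n the critical count is
    the smallest k with ``P(X >= k | p0) <= alpha`` and power is
    ``P(X >= k | p0 + g)``.  Because the achievable type-I level is a
    sawtooth in n, exact power is not monotone and the solver scans n
    upward.

    ``method="normal"`` uses the large-sample approximation with the
    variance evaluated at the alternative proportion,

        n = ceil( (z_alpha + z_beta)^2 * p1 * (1 - p1) / g^2 ),

    the convention used by common a priori power tools for this design.
    """
    if not (0 < g < 1 - p0):
        raise ValueError("need 0 < g < 1 - p0")
    p1 = p0 + g
    if method == "normal":
        za = sps.norm.isf(alpha)
        zb = sps.norm.isf(1 - power)
        return int(math.ceil((za + zb) ** 2 * p1 * (1 - p1) / g**2))
    if method != "exact":
        raise ValueError("method must be 'exact' or 'normal'")
    for n in range(1, n_max + 1):
        k = _binom_critical_k(n, alpha, p0)
        if k > n:
            continue
        if sps.binom.sf(k - 1, n, p1) >= power:
            return n
    raise RuntimeError("no n found below n_max")


def sequential_bf_stop(bf_trace: Sequence[float], rule: StoppingRule) -> SequentialDecision:
    """Evaluate a Bayesian stopping rule on per-batch Bayes factors.

    ``bf_trace[i]`` is the BF10 computed on all data collected up to and
    including batch i.  Sampling stops at the first batch whose BF crosses
    either threshold; otherwise it continues until the participant cap.
    """
    bf_trace = list(bf_trace)
    if not bf_trace:
        raise ValueError("empty Bayes-factor trace")
    n = 0
    for i, bf in enumerate(bf_trace):
        n += rule.batch_size(i)
        if bf >= rule.bf_upper:
            return SequentialDecision("stop_h1", n_used=n, n_batches=i + 1, bf_final=bf)
        if bf <= rule.bf_lower:
            return SequentialDecision("stop_h0", n_used=n, n_batches=i + 1, bf_final=bf)
        if n >= rule.n_max:
            return SequentialDecision("cap_reached", n_used=n, n_batches=i + 1, bf_final=bf)
    return SequentialDecision("continue", n_used=n, n_batches=len(bf_trace), bf_final=bf_trace[-1])


def pearson_r(x, y) -> tuple[float, float]:
    """Product-moment correlation with a two-sided t-based p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("length mismatch")
    n = x.size
    if n < 3:
        raise ValueError("need at least 3 paired observations")
    xc = x - x.mean()
    yc = y - y.mean()
    sx = math.sqrt(float(xc @ xc))
    sy = math.sqrt(float(yc @ yc))
    if sx == 0 or sy == 0:
        raise ValueError("zero variance")
    r = float(xc @ yc) / (sx * sy)
    r = max(-1.0, min(1.0, r))
    if abs(r) == 1.0:
        return r, 0.0
    t = r * math.sqrt((n - 2) / (1 - r * r))
    p = float(2.0 * sps.t.sf(abs(t), n - 2))
    return r, p


def bonferroni(p_values, alpha: float = 0.05) -> tuple[np.ndarray, float]:
    """Family-wise significance flags at the Bonferroni-adjusted threshold.

    Returns ``(flags, threshold)`` with ``threshold = alpha / m``.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        raise ValueError("need at least one p-value")
    thr = alpha / p.size
    return p < thr, float(thr)
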