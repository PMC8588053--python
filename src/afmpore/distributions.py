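"""Moment summaries, normality screening, Gamma fitting and two-sample tests.

Pore-radius distributions from AFM sampling are right-skewed, so the
analysis screens each dataset for normality with the Jarque–Bera (JB)
statistic before choosing between parametric (t-test after a variance
check) and non-parametric (Kruskal–Wallis) two-sample comparison, and
models the radii with a two-parameter Gamma distribution for the
parametric bootstrap.

Skewness and kurtosis use the uncorrected (population-style) central
moment estimators ``b1 = m3 / m2^1.5`` and ``b2 = m4 / m2^2`` (plain, not
excess, kurtosis: Gaussian data give ``b2 = 3``).  The JB statistic is

    JB = n * (b1^2 / 6 + (b2 - 3)^2 / 24)

and is compared against finite-sample Monte-Carlo critical values rather
than the asymptotic chi-squared(2) quantile, which is anticonservative at
the sample sizes in play (n = 60 and n = 304).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats


@dataclass(frozen=True)
class MomentSummary:
    """Sample size, mean, skewness and (non-excess) kurtosis of one dataset."""

    n: int
    mean: float
    skewness_b1: float
    kurtosis_b2: float

    def __post_init__(self):
        if self.n < 2:
            raise ValueError("moment summary requires n >= 2")
        # moment inequality b2 >= 1 + b1^2 holds for any real sample
        if self.kurtosis_b2 < 1 + self.skewness_b1**2 - 1e-9:
            raise ValueError("kurtosis violates the moment inequality b2 >= 1 + b1^2")


@dataclass(frozen=True)
class JBResult:
    statistic: float
    critical_value: float

    @property
    def passes_normality(self) -> bool:
        return self.statistic <= self.critical_value


@dataclass(frozen=True)
class GammaParams:
    """Shape/scale parametrisation of the Gamma distribution.

    Density ``f(x) = x^(a-1) exp(-x/b) / (b^a Gamma(a))`` for x >= 0, with
    mean ``a*b``, variance ``a*b^2`` and skewness ``2/sqrt(a)``.
    """

    shape_a: float
    scale_b: float

    def __post_init__(self):
        if self.shape_a <= 0 or self.scale_b <= 0:
            raise ValueError(
                f"Gamma shape and scale must be > 0, got a={self.shape_a}, b={self.scale_b}"
            )

    @property
    def mean(self) -> float:
        return self.shape_a * self.scale_b

    @property
    def variance(self) -> float:
        return self.shape_a * self.scale_b**2

    @property
    def skewness(self) -> float:
        return 2.0 / np.sqrt(self.shape_a)

    def log_likelihood(self, values) -> float:
        return float(
            np.sum(stats.gamma.logpdf(np.asarray(values, float), self.shape_a, scale=self.scale_b))
        )


@dataclass(frozen=True)
class KWResult:
    h_statistic: float
    dof: int
    p_value: float


@dataclass(frozen=True)
class DiscriminationResult:
    """Outcome of the normality-gated two-sample comparison.

    ``branch`` is one of ``"t-pooled"``, ``"t-welch"`` or
    ``"kruskal-wallis"``; the parametric branches are only reachable when
    both samples pass the JB screen.
    """

    branch: str
    statistic: float
    p_value: float
    jb_a: JBResult
    jb_b: JBResult
    levene_p: float | None


def sample_moments(values: Sequence[float]) -> MomentSummary:
    """Mean, skewness and kurtosis with uncorrected central-moment estimators."""
    x = np.asarray(values, dtype=float)
    if x.ndim != 1 or x.size < 2:
        raise ValueError("sample_moments requires a 1-D sample with n >= 2")
    if not np.all(np.isfinite(x)):
        raise ValueError("sample contains non-finite values")
    xc = x - x.mean()
    m2 = np.mean(xc**2)
    if m2 == 0:
        raise ValueError("degenerate sample: zero variance")
    b1 = np.mean(xc**3) / m2**1.5
    b2 = np.mean(xc**4) / m2**2
    return MomentSummary(n=x.size, mean=float(x.mean()), skewness_b1=float(b1), kurtosis_b2=float(b2))


def jarque_bera_statistic(n: int, skewness_b1: float, kurtosis_b2: float) -> float:
    """JB = n*(b1^2/6 + (b2-3)^2/24) from printed or computed moments."""
    return n * (skewness_b1**2 / 6.0 + (kurtosis_b2 - 3.0) ** 2 / 24.0)


def jarque_bera(moments: MomentSummary, critical_value: float) -> JBResult:
    """Jarque–Bera normality screen against a supplied critical value."""
    stat = jarque_bera_statistic(moments.n, moments.skewness_b1, moments.kurtosis_b2)
    return JBResult(statistic=float(stat), critical_value=float(critical_value))


def _jb_rows(x: np.ndarray) -> np.ndarray:
    """JB statistic per row of a (replicates, n) matrix."""
    xc = x - x.mean(axis=1, keepdims=True)
    m2 = np.mean(xc**2, axis=1)
    b1 = np.mean(xc**3, axis=1) / m2**1.5
    b2 = np.mean(xc**4, axis=1) / m2**2
    return x.shape[1] * (b1**2 / 6.0 + (b2 - 3.0) ** 2 / 24.0)


def jb_critical(
    n: int,
    alpha: float = 0.05,
    replicates: int = 100_000,
    seed: int = 0,
) -> float:
    """Finite-sample Monte-Carlo critical value of the JB statistic.

    Simulates standard-normal samples of size ``n`` and returns the
    ``1 - alpha`` quantile of JB.  Converges to the chi-squared(2)
    quantile (5.99 at alpha = 0.05) as ``n`` grows, but is noticeably
    smaller at moderate n (about 5.1 at n = 60, 5.8 at n = 304).
    """
    if n < 8:
        raise ValueError("jb_critical requires n >= 8")
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    if replicates < 10_000:
        raise ValueError("at least 1e4 replicates are needed for a stable quantile")
    rng = np.random.default_rng(seed)
    chunk = max(1, 4_000_000 // n)
    out = []
    remaining = replicates
    while remaining > 0:
        m = min(chunk, remaining)
        out.append(_jb_rows(rng.standard_normal((m, n))))
        remaining -= m
    return float(np.quantile(np.concatenate(out), 1.0 - alpha))


def kruskal_wallis(groups: Sequence[Sequence[float]]) -> KWResult:
    """Kruskal–Wallis rank test (midrank tie correction, chi-squared p-value)."""
    if len(groups) < 2:
        raise ValueError("kruskal_wallis requires at least two groups")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if any(a.size == 0 for a in arrays):
        raise ValueError("all groups must be non-empty")
    pooled = np.concatenate(arrays)
    dof = len(arrays) - 1
    if np.all(pooled == pooled[0]):
        return KWResult(h_statistic=0.0, dof=dof, p_value=1.0)
    h, p = stats.kruskal(*arrays)
    return KWResult(h_statistic=float(h), dof=dof, p_value=float(p))


def gamma_fit_moments(mean: float, skewness: float) -> GammaParams:
    """Invert Gamma moment identities: shape = (2/skew)^2, scale = mean/shape.

    Used to reconstruct generating parameters from a published (mean,
    skewness) pair when raw data are unavailable.
    """
    if mean <= 0:
        raise ValueError("mean must be > 0")
    if skewness <= 0:
        raise ValueError("skewness must be > 0 for the Gamma family")
    shape = (2.0 / skewness) ** 2
    return GammaParams(shape_a=shape, scale_b=mean / shape)


def gamma_fit_mle(values: Sequence[float]) -> GammaParams:
    """Maximum-likelihood Gamma fit (location fixed at zero).

    The optimum is at least as likely as the method-of-moments start; the
    profile likelihood in the shape is unimodal so the fit is reliable for
    any non-degenerate positive sample.
    """
    x = np.asarray(values, dtype=float)
    if x.size < 10:
        raise ValueError("gamma_fit_mle requires n >= 10")
    if np.any(x <= 0):
        raise ValueError("Gamma fitting requires strictly positive values")
    if np.var(x) == 0:
        raise ValueError("degenerate sample: zero variance")
    shape, _, scale = stats.gamma.fit(x, floc=0)
    return GammaParams(shape_a=float(shape), scale_b=float(scale))


def pairwise_discrimination(
    values_a: Sequence[float],
    values_b: Sequence[float],
    alpha: float = 0.05,
    jb_critical_a: float | None = None,
    jb_critical_b: float | None = None,
    jb_replicates: int = 20_000,
    seed: int = 0,
) -> DiscriminationResult:
    """Normality-gated two-sample location comparison.

    Both samples are screened with the JB test at the finite-sample
    critical value for their own n (Monte-Carlo, unless supplied).  If
    both pass, variances are compared with the Brown–Forsythe variant of
    Levene's test (absolute deviations from the median) and a pooled or
    Welch t-test follows; otherwise the Kruskal–Wallis rank test is used
    on the two groups.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    crit_a = jb_critical_a if jb_critical_a is not None else jb_critical(
        a.size, alpha, max(jb_replicates, 10_000), seed
    )
    crit_b = jb_critical_b if jb_critical_b is not None else jb_critical(
        b.size, alpha, max(jb_replicates, 10_000), seed + 1
    )
    jb_a = jarque_bera(sample_moments(a), crit_a)
    jb_b = jarque_bera(sample_moments(b), crit_b)
    if jb_a.passes_normality and jb_b.passes_normality:
        _, lev_p = stats.levene(a, b, center="median")
        equal_var = lev_p > alpha
        stat, p = stats.ttest_ind(a, b, equal_var=equal_var)
        branch = "t-pooled" if equal_var else "t-welch"
        return DiscriminationResult(
            branch=branch, statistic=float(stat), p_value=float(p),
            jb_a=jb_a, jb_b=jb_b, levene_p=float(lev_p),
        )
    kw = kruskal_wallis([a, b])
    return DiscriminationResult(
        branch="kruskal-wallis", statistic=kw.h_statistic, p_value=kw.p_value,
        jb_a=jb_a, jb_b=jb_b, levene_p=None,
    )
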