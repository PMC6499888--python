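"""Statistical layer: BCa bootstrap CIs, one-way ANOVA with Tukey-Kramer
post-hoc comparisons, paired t-tests, and the JZS default-prior Bayes-factor
t-test.

The Bayes factor follows the Jeffreys-Zellner-Siow setup for a one-sample
(paired-difference) t-test: a Cauchy(0, r) prior on the standardised effect
size under the alternative against a point null, with r = sqrt(2)/2 by
default.  BF10 is the ratio of the marginal likelihood under the alternative
to the null likelihood, evaluated by numerical quadrature of the equivalent
g-prior integral.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import integrate, stats as sps

DEFAULT_PRIOR_SCALE = math.sqrt(2.0) / 2.0
DEFAULT_N_BOOT = 2000


class StatsError(ValueError):
    """Invalid input to a statistical routine."""


# ---------------------------------------------------------------------------
# BCa bootstrap
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BootstrapCI:
    """A bias-corrected and accelerated percentile bootstrap interval."""

    point: float
    lower: float
    upper: float
    n_boot: int = DEFAULT_N_BOOT
    confidence_level: float = 0.95
    method: str = "BCa"
    seed: int | None = None

    def spans_zero(self) -> bool:
        return self.lower <= 0.0 <= self.upper


def bca_bootstrap(values, statistic=np.mean, n_boot: int = DEFAULT_N_BOOT,
                  seed: int | None = None,
                  confidence_level: float = 0.95) -> BootstrapCI:
    """95% (by default) BCa bootstrap CI of ``statistic`` over ``values``.

    Bias correction comes from the bootstrap distribution and acceleration
    from jackknife skewness.  Degenerate (constant) input collapses to the
    point interval with a warning; in the rare pathological resample where
    the BCa bounds exclude the point estimate, the interval is widened to
    include it, again with a warning.
    """
    data = np.asarray(values, dtype=float)
    if data.ndim != 1 or len(data) < 2:
        raise StatsError("need at least two values")
    if not np.all(np.isfinite(data)):
        raise StatsError("values must be finite")
    point = float(statistic(data))
    if np.ptp(data) == 0.0:
        warnings.warn("constant input: degenerate bootstrap interval",
                      stacklevel=2)
        return BootstrapCI(point=point, lower=point, upper=point,
                           n_boot=n_boot, confidence_level=confidence_level,
                           seed=seed)
    rng = np.random.default_rng(seed)
    res = sps.bootstrap((data,), statistic, n_resamples=n_boot,
                        confidence_level=confidence_level, method="BCa",
                        vectorized=False, rng=rng)
    lower = float(res.confidence_interval.low)
    upper = float(res.confidence_interval.high)
    if not np.isfinite(lower) or not np.isfinite(upper) \
            or not (lower <= point <= upper):
        warnings.warn("BCa interval did not bracket the point estimate; "
                      "widening", stacklevel=2)
        lower = min(lower, point) if np.isfinite(lower) else point
        upper = max(upper, point) if np.isfinite(upper) else point
    return BootstrapCI(point=point, lower=lower, upper=upper, n_boot=n_boot,
                       confidence_level=confidence_level, seed=seed)


# ---------------------------------------------------------------------------
# one-way ANOVA and Tukey-Kramer
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AnovaResult:
    """One-way between-groups ANOVA decomposition."""

    F: float
    df_between: int
    df_within: int
    p: float
    group_means: tuple[float, ...]
    ss_between: float
    ss_within: float

    @property
    def ss_total(self) -> float:
        return self.ss_between + self.ss_within


def _check_groups(groups) -> list[np.ndarray]:
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if len(arrays) < 2:
        raise StatsError("need at least two groups")
    for i, g in enumerate(arrays):
        if g.ndim != 1 or len(g) < 2:
            raise StatsError(f"group {i} needs at least two values")
        if not np.all(np.isfinite(g)):
            raise StatsError(f"group {i} contains non-finite values")
    return arrays


def oneway_anova(groups) -> AnovaResult:
    """Standard between/within sum-of-squares decomposition.

    ``k`` groups pooled into a single factor give ``df = (k-1, N-k)``.  When
    every observation is identical the 0/0 statistic is defined as F = 0
    (with a warning).
    """
    arrays = _check_groups(groups)
    all_values = np.concatenate(arrays)
    grand = all_values.mean()
    means = [g.mean() for g in arrays]
    ss_between = float(sum(len(g) * (m - grand) ** 2
                           for g, m in zip(arrays, means)))
    ss_within = float(sum(((g - m) ** 2).sum()
                          for g, m in zip(arrays, means)))
    df_between = len(arrays) - 1
    df_within = len(all_values) - len(arrays)
    if ss_within == 0.0:
        if ss_between == 0.0:
            warnings.warn("all values identical: defining F = 0", stacklevel=2)
            F, p = 0.0, 1.0
        else:
            F, p = float("inf"), 0.0
    else:
        F = (ss_between / df_between) / (ss_within / df_within)
        p = float(sps.f.sf(F, df_between, df_within))
    return AnovaResult(F=float(F), df_between=df_between, df_within=df_within,
                       p=p, group_means=tuple(float(m) for m in means),
                       ss_between=ss_between, ss_within=ss_within)


def tukey_kramer(groups) -> "pd.DataFrame":
    """All pairwise comparisons via the studentized range distribution.

    Uses pooled within-group variance with ``N - k`` degrees of freedom and
    the Kramer harmonic form for unequal group sizes.  Returns a table with
    one row per pair (i < j): mean difference and adjusted p-value.
    """
    import pandas as pd  # local import keeps scipy-only callers light
    arrays = _check_groups(groups)
    res = sps.tukey_hsd(*arrays)
    rows = []
    for i in range(len(arrays)):
        for j in range(i + 1, len(arrays)):
            rows.append((i, j,
                         float(arrays[i].mean() - arrays[j].mean()),
                         float(res.pvalue[i, j])))
    return pd.DataFrame(rows, columns=["group_i", "group_j", "mean_diff",
                                       "p_adj"])


def paired_ttest(differences) -> tuple[float, int, float]:
    """Two-sided one-sample t-test on paired differences: (t, df, p)."""
    data = np.asarray(differences, dtype=float)
    if len(data) < 2:
        raise StatsError("need at least two differences")
    t, p = sps.ttest_1samp(data, 0.0)
    return float(t), len(data) - 1, float(p)


# ---------------------------------------------------------------------------
# JZS Bayes factor
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BayesFactorResult:
    """JZS Bayes factor for a one-sample t-test."""

    bf10: float
    t: float
    n: int
    prior_scale: float

    @property
    def bf01(self) -> float:
        return 1.0 / self.bf10


def jzs_bf_from_t(t: float, n: int,
                  prior_scale: float = DEFAULT_PRIOR_SCALE) -> float:
    """JZS BF10 from a one-sample t statistic with n observations.

    Marginalises the g-prior representation of the Cauchy(0, r) effect-size
    prior: the alternative's marginal likelihood is the integral over
    g ~ InverseGamma(1/2, 1/2) of the t likelihood with variance inflation
    1 + n r^2 g, divided by the point-null t likelihood.
    """
    if n < 2:
        raise StatsError("need n >= 2")
    nu = n - 1
    r2 = prior_scale ** 2
    t2 = float(t) ** 2

    def integrand(g: float) -> float:
        c = 1.0 + n * r2 * g
        log_term = (-0.5 * math.log(c)
                    - (nu + 1) / 2.0 * math.log1p(t2 / (c * nu))
                    - 0.5 * math.log(2.0 * math.pi)
                    - 1.5 * math.log(g) - 1.0 / (2.0 * g))
        return math.exp(log_term)

    numerator, _ = integrate.quad(integrand, 0.0, np.inf, limit=200)
    log_null = -(nu + 1) / 2.0 * math.log1p(t2 / nu)
    return numerator / math.exp(log_null)


def jzs_bf(differences, prior_scale: float = DEFAULT_PRIOR_SCALE
           ) -> BayesFactorResult:
    """JZS Bayes factor for paired differences (two-sided, default prior)."""
    data = np.asarray(differences, dtype=float)
    if len(data) < 2:
        raise StatsError("need at least two differences")
    sd = data.std(ddof=1)
    if sd == 0.0:
        raise StatsError("zero-variance differences: t is undefined")
    t = data.mean() / (sd / math.sqrt(len(data)))
    return BayesFactorResult(bf10=jzs_bf_from_t(t, len(data), prior_scale),
                             t=float(t), n=len(data),
                             prior_scale=prior_scale)


def bf_label(bf10: float) -> tuple[str, str]:
    """Conventional evidence label for a Bayes factor.

    Returns ``(strength, direction)`` with strength in {"anecdotal",
    "moderate", "strong"} applied to BF10 or its reciprocal, and direction
    in {"alternative", "null"}.
    """
    if bf10 <= 0:
        raise StatsError("BF10 must be positive")
    direction = "alternative" if bf10 >= 1.0 else "null"
    magnitude = bf10 if bf10 >= 1.0 else 1.0 / bf10
    if magnitude < 3.0:
        return "anecdotal", direction
    if magnitude <= 10.0:
        return "moderate", direction
    return "strong", direction
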