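"""Inference on difference scores: bootstrap CIs, nonparametric tests,
effect sizes, and a one-sample random-intercept linear mixed model.

The LMM is `score ~ 1 + (1 | subject)` fit by REML, with a Satterthwaite
approximation for the t degrees of freedom and a likelihood-ratio test of the
intercept from maximum-likelihood refits.  The model is small enough that it
is fit directly from its closed-form marginal likelihood (per-subject sums of
squares); statsmodels' MixedLM serves as an independent cross-check in the
test suite rather than as the fitting engine, because it exposes neither
Satterthwaite degrees of freedom nor a fixed-intercept LRT.
"""

from __future__ import annotations

import enum
import warnings
from dataclasses import dataclass
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats as sps

from .errors import ConvergenceError, GazelexError

# ---------------------------------------------------------------------------
# Bootstrap
# ---------------------------------------------------------------------------


class ResamplingUnit(str, enum.Enum):
    SUBJECT = "SUBJECT"
    ITEM = "ITEM"


@dataclass(frozen=True)
class BootstrapResult:
    estimate: float
    ci_low: float
    ci_high: float
    level: float
    n_reps: int
    seed: Optional[int]
    resampling_unit: ResamplingUnit


def percentile_bootstrap_ci(
    values: Sequence[float],
    n_reps: int = 10_000,
    seed: Optional[int] = None,
    statistic: Callable[[np.ndarray], float] = np.mean,
    level: float = 0.95,
    resampling_unit: ResamplingUnit = ResamplingUnit.SUBJECT,
) -> BootstrapResult:
    """Percentile bootstrap CI for a statistic of per-unit values.

    Units (subjects, or subjects-within-item) are resampled with replacement;
    the interval is the (2.5, 97.5) percentile of the resampled statistics at
    the default level.
    """
    arr = np.asarray(values, dtype=float)
    if arr.ndim != 1 or len(arr) < 2:
        raise GazelexError("bootstrap requires a 1-d sample of at least 2 units")
    if n_reps < 1000:
        raise GazelexError("n_reps must be at least 1000 for a stable percentile CI")
    if np.ptp(arr) == 0:
        warnings.warn("all bootstrap values identical; interval is degenerate")
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, len(arr), size=(n_reps, len(arr)))
    reps = np.asarray([statistic(arr[row]) for row in idx]) \
        if statistic is not np.mean else arr[idx].mean(axis=1)
    alpha = (1.0 - level) / 2.0
    lo, hi = np.quantile(reps, [alpha, 1.0 - alpha])
    return BootstrapResult(
        estimate=float(statistic(arr)),
        ci_low=float(lo),
        ci_high=float(hi),
        level=level,
        n_reps=n_reps,
        seed=seed,
        resampling_unit=resampling_unit,
    )


def bootstrap_item_grand_mean(
    rows: pd.DataFrame,
    n_reps: int = 10_000,
    seed: Optional[int] = None,
    level: float = 0.95,
) -> BootstrapResult:
    """Bootstrap the grand mean of item means by resampling subjects.

    ``rows`` is a PairScore table (subject_id, word_pair_id, score).  Each
    replicate resamples subjects with replacement and recomputes item means
    over the resampled subjects, then their grand mean — the exchangeable
    unit stays the subject, matching the other bootstraps.
    """
    mat = rows.pivot_table(
        index="subject_id", columns="word_pair_id", values="score"
    ).to_numpy()  # (S, I) with NaN where a subject has no score for an item
    n_subj = mat.shape[0]
    if n_subj < 2:
        raise GazelexError("item-mean bootstrap requires at least 2 subjects")
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, n_subj, size=(n_reps, n_subj))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN item in a draw
        reps = np.nanmean(np.nanmean(mat[idx], axis=1), axis=1)
    alpha = (1.0 - level) / 2.0
    lo, hi = np.quantile(reps, [alpha, 1.0 - alpha])
    est = rows.groupby("word_pair_id")["score"].mean().mean()
    return BootstrapResult(
        estimate=float(est),
        ci_low=float(lo),
        ci_high=float(hi),
        level=level,
        n_reps=n_reps,
        seed=seed,
        resampling_unit=ResamplingUnit.SUBJECT,
    )


# ---------------------------------------------------------------------------
# Nonparametric tests and effect sizes
# ---------------------------------------------------------------------------


class TestMethod(str, enum.Enum):
    WILCOXON = "WILCOXON"
    EXACT_BINOMIAL = "EXACT_BINOMIAL"
    KENDALL = "KENDALL"


@dataclass(frozen=True)
class TestResult:
    statistic: float
    p_value: float
    sidedness: str
    method: TestMethod
    n: int


def wilcoxon_signed_rank(
    values: Sequence[float], null_center: float = 0.0
) -> TestResult:
    """Two-sided Wilcoxon signed-rank test against a point null.

    Zeros (values equal to the null center) are dropped, per the classical
    convention.  The exact null distribution is used for n <= 25 (when ranks
    are untied); larger samples use the normal approximation with continuity
    correction.
    """
    devs = np.asarray(values, dtype=float) - null_center
    devs = devs[devs != 0]
    n = len(devs)
    if n < 2:
        raise GazelexError("Wilcoxon test requires >= 2 nonzero deviations")
    ranks = sps.rankdata(np.abs(devs))
    has_ties = len(np.unique(ranks)) != n
    method = "exact" if (n <= 25 and not has_ties) else "approx"
    res = sps.wilcoxon(
        devs, alternative="two-sided", method=method, correction=(method == "approx")
    )
    return TestResult(
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        sidedness="two-sided",
        method=TestMethod.WILCOXON,
        n=n,
    )


def exact_sign_test(n_positive: int, n_total: int) -> TestResult:
    """Exact two-sided binomial (sign) test of P(positive) = 1/2.

    Two-sidedness follows the minimum-likelihood convention: the p-value sums
    the probabilities of all outcomes no more probable than the observed one.
    """
    if not 0 <= n_positive <= n_total:
        raise GazelexError("need 0 <= n_positive <= n_total")
    if n_total == 0:
        raise GazelexError("sign test undefined for n_total = 0")
    res = sps.binomtest(n_positive, n_total, p=0.5, alternative="two-sided")
    return TestResult(
        statistic=float(n_positive),
        p_value=float(res.pvalue),
        sidedness="two-sided",
        method=TestMethod.EXACT_BINOMIAL,
        n=n_total,
    )


def one_sample_cohens_d(values: Sequence[float]) -> float:
    """Mean over sample standard deviation (n-1 denominator)."""
    arr = np.asarray(values, dtype=float)
    if len(arr) < 2:
        raise GazelexError("Cohen's d requires >= 2 values")
    sd = arr.std(ddof=1)
    if sd == 0:
        raise GazelexError("Cohen's d undefined for zero spread")
    return float(arr.mean() / sd)


def kendall_tau(x: Sequence[float], y: Sequence[float]) -> TestResult:
    """Kendall's tau-b with a two-sided p (exact for small untied samples)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise GazelexError("kendall_tau requires equal-length vectors of >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise GazelexError("kendall_tau undefined for a constant vector")
    res = sps.kendalltau(x, y)
    return TestResult(
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        sidedness="two-sided",
        method=TestMethod.KENDALL,
        n=len(x),
    )


# ---------------------------------------------------------------------------
# One-sample random-intercept linear mixed model
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class LmmResult:
    intercept: float
    intercept_se: float
    ci_low: float
    ci_high: float
    t_value: float
    df: float  # Satterthwaite
    p_value: float
    subject_var: float
    residual_var: float
    lrt_chisq: float
    lrt_df: int
    lrt_p: float
    loglik_reml: float


def _lmm_suffstats(scores: pd.DataFrame):
    g = scores.groupby("subject_id")["score"]
    n_i = g.count().to_numpy(dtype=float)
    ybar_i = g.mean().to_numpy(dtype=float)
    ss_i = (g.apply(lambda v: float(((v - v.mean()) ** 2).sum()))).to_numpy(dtype=float)
    return n_i, ybar_i, ss_i


def _lmm_neg_ll(theta, n_i, ybar_i, ss_i, reml: bool, mu: Optional[float]):
    """Negative marginal (or REML) log-likelihood; mu=None profiles the GLS mean."""
    tau2, sig2 = np.exp(theta)
    d_i = sig2 + n_i * tau2
    w_i = n_i / d_i
    if mu is None:
        mu = float(np.sum(w_i * ybar_i) / np.sum(w_i))
    n_tot = n_i.sum()
    ll = -0.5 * (
        n_tot * np.log(2 * np.pi)
        + np.sum((n_i - 1) * np.log(sig2) + np.log(d_i))
        + np.sum(ss_i) / sig2
        + np.sum(w_i * (ybar_i - mu) ** 2)
    )
    if reml:
        ll += -0.5 * np.log(np.sum(w_i)) + 0.5 * np.log(2 * np.pi)
    return -ll


def _fit_variances(n_i, ybar_i, ss_i, reml: bool, mu: Optional[float]):
    y_all_var = max(np.var(np.repeat(ybar_i, 1)), 1e-6)
    x0 = np.log([y_all_var / 2 + 1e-6, y_all_var / 2 + 1e-6])
    res = optimize.minimize(
        _lmm_neg_ll,
        x0,
        args=(n_i, ybar_i, ss_i, reml, mu),
        method="Nelder-Mead",
        options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 2000},
    )
    if not res.success:
        raise ConvergenceError("LMM variance optimization failed", trace=res)
    tau2, sig2 = np.exp(res.x)
    return tau2, sig2, -res.fun, res


def _satterthwaite_df(n_i, ybar_i, ss_i, tau2, sig2) -> float:
    """Satterthwaite df for the intercept t statistic.

    df = 2 Var(mu_hat)^2 / (g' A g) with g the gradient of Var(mu_hat) in the
    variance components and A their REML asymptotic covariance (inverse
    observed information, by finite differences).
    """

    def var_mu(theta):
        t2, s2 = theta
        return 1.0 / np.sum(n_i / (s2 + n_i * t2))

    theta = np.array([tau2, sig2])
    h = np.maximum(1e-7, 1e-5 * np.maximum(theta, 1e-4))
    g = np.zeros(2)
    for k in range(2):
        e = np.zeros(2)
        e[k] = h[k]
        g[k] = (var_mu(theta + e) - var_mu(np.maximum(theta - e, 1e-12))) / (
            theta[k] + h[k] - max(theta[k] - h[k], 1e-12)
        )

    def nll(theta_lin):
        t2, s2 = np.maximum(theta_lin, 1e-12)
        return _lmm_neg_ll(np.log([t2, s2]), n_i, ybar_i, ss_i, True, None)

    # observed information in the linear parametrization
    H = np.zeros((2, 2))
    for a in range(2):
        for b in range(2):
            ea = np.zeros(2)
            eb = np.zeros(2)
            ea[a] = h[a]
            eb[b] = h[b]
            H[a, b] = (
                nll(theta + ea + eb)
                - nll(theta + ea - eb)
                - nll(theta - ea + eb)
                + nll(theta - ea - eb)
            ) / (4 * h[a] * h[b])
    try:
        A = np.linalg.inv(H)
        denom = float(g @ A @ g)
    except np.linalg.LinAlgError:
        denom = np.nan
    v = var_mu(theta)
    n_subj = len(n_i)
    n_tot = int(n_i.sum())
    if not np.isfinite(denom) or denom <= 0:
        return float(n_subj - 1)
    df = 2 * v**2 / denom
    return float(np.clip(df, 1.0, n_tot - 1))


def fit_intercept_lmm(scores: pd.DataFrame) -> LmmResult:
    """Fit `score ~ 1 + (1 | subject_id)` to a PairScore table.

    REML point estimates and a Satterthwaite-df t interval for the intercept;
    the LRT of the intercept refits both the full and the zero-mean null
    model by maximum likelihood.
    """
    if scores["subject_id"].nunique() < 2:
        raise GazelexError("intercept LMM requires >= 2 subjects")
    n_i, ybar_i, ss_i = _lmm_suffstats(scores)

    tau2, sig2, ll_reml, _ = _fit_variances(n_i, ybar_i, ss_i, reml=True, mu=None)
    w_i = n_i / (sig2 + n_i * tau2)
    mu = float(np.sum(w_i * ybar_i) / np.sum(w_i))
    se = float(np.sqrt(1.0 / np.sum(w_i)))
    df = _satterthwaite_df(n_i, ybar_i, ss_i, tau2, sig2)
    t = mu / se
    p = 2 * sps.t.sf(abs(t), df)
    tcrit = sps.t.ppf(0.975, df)

    _, _, ll_full, _ = _fit_variances(n_i, ybar_i, ss_i, reml=False, mu=None)
    _, _, ll_null, _ = _fit_variances(n_i, ybar_i, ss_i, reml=False, mu=0.0)
    lrt = max(0.0, 2 * (ll_full - ll_null))

    return LmmResult(
        intercept=mu,
        intercept_se=se,
        ci_low=mu - tcrit * se,
        ci_high=mu + tcrit * se,
        t_value=float(t),
        df=df,
        p_value=float(p),
        subject_var=float(tau2),
        residual_var=float(sig2),
        lrt_chisq=float(lrt),
        lrt_df=1,
        lrt_p=float(sps.chi2.sf(lrt, 1)),
        loglik_reml=float(ll_reml),
    )
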