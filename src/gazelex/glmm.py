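"""Pre/post-naming binomial mixed-effects logit model.

Each usable trial contributes up to two binomial observations: the counts of
20 ms gaze bins on the target (successes) vs. the distractor (failures) in
the pre-naming window and in the analysis window.  AWAY bins never enter.
The model is

    logit P(bin on target) = beta0 + beta_post * POST [+ age terms]
                             + b_subject [+ b_item]

with independent Gaussian random intercepts, fit by maximizing the Laplace
approximation to the marginal likelihood (the standard approximation for
binomial mixed models).  The exponentiated phase coefficient is the "phase
odds ratio": the multiplicative change in the odds of an on-display gaze bin
being on the target once the word has been heard.

Wald statistics condition on the estimated variance components; nested models
are compared by likelihood-ratio tests on the Laplace log-likelihoods.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, special
from scipy import stats as sps

from .errors import ConvergenceError, GazelexError
from .types import Role
from .windowing import ANALYSIS, DEFAULT_BIN_MS, PRENAMING, ClassifiedSession, bin_window

PHASE_PRE = "PRE"
PHASE_POST = "POST"


def build_phase_counts(
    classified: Sequence[ClassifiedSession],
    bin_ms: float = DEFAULT_BIN_MS,
) -> pd.DataFrame:
    """Per-(trial, phase) binomial counts of TARGET vs DISTRACTOR bins.

    Rows with zero on-display bins in a phase are dropped (they carry no
    binomial information).  Only trials that survived exclusion contribute.
    """
    rows = []
    for cs in classified:
        sid = cs.session.subject.subject_id
        age = cs.session.subject.age_months
        for trial in cs.usable:
            for phase, window in ((PHASE_PRE, PRENAMING), (PHASE_POST, ANALYSIS)):
                series = bin_window(trial, window, bin_ms)
                n_t = series.count(Role.TARGET)
                n_d = series.count(Role.DISTRACTOR)
                if n_t + n_d == 0:
                    continue
                rows.append(
                    {
                        "subject_id": sid,
                        "item_id": trial.spec.word_pair_id,
                        "trial_id": trial.spec.trial_id,
                        "phase": phase,
                        "n_target": n_t,
                        "n_distractor": n_d,
                        "age_months": age,
                    }
                )
    return pd.DataFrame(
        rows,
        columns=[
            "subject_id",
            "item_id",
            "trial_id",
            "phase",
            "n_target",
            "n_distractor",
            "age_months",
        ],
    )


@dataclass(frozen=True)
class GlmmResult:
    terms: tuple[str, ...]
    coef: np.ndarray
    se: np.ndarray
    odds_ratios: np.ndarray
    or_ci_low: np.ndarray
    or_ci_high: np.ndarray
    wald_chisq: np.ndarray
    wald_p: np.ndarray
    subject_sd: float
    item_sd: Optional[float]
    loglik: float
    n_obs: int
    n_params: int
    converged: bool
    message: str = ""
    ranef_subject: Optional[dict[str, float]] = None
    ranef_item: Optional[dict[str, float]] = None

    def coef_for(self, term: str) -> float:
        return float(self.coef[self.terms.index(term)])

    def or_for(self, term: str) -> float:
        return float(self.odds_ratios[self.terms.index(term)])

    def summary_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "term": self.terms,
                "estimate": self.coef,
                "se": self.se,
                "odds_ratio": self.odds_ratios,
                "or_ci_low": self.or_ci_low,
                "or_ci_high": self.or_ci_high,
                "wald_chisq": self.wald_chisq,
                "p": self.wald_p,
            }
        )


def _design(
    counts: pd.DataFrame, include_age: bool, standardize_age: bool
) -> tuple[np.ndarray, tuple[str, ...]]:
    post = (counts["phase"] == PHASE_POST).to_numpy(dtype=float)
    cols = [np.ones(len(counts)), post]
    terms = ["(Intercept)", "phase_post"]
    if include_age:
        age = counts["age_months"].to_numpy(dtype=float)
        if standardize_age:
            # standardize over subjects, not rows, so heavy lookers don't
            # dominate the age scale
            per_subj = counts.groupby("subject_id")["age_months"].first()
            mu, sd = per_subj.mean(), per_subj.std(ddof=1)
            age = (age - mu) / sd
        cols += [age, post * age]
        terms += ["age", "phase_post:age"]
    return np.column_stack(cols), tuple(terms)


def _log1pexp(x: np.ndarray) -> np.ndarray:
    return np.logaddexp(0.0, x)


class _LaplaceProblem:
    """Closure holding data arrays and a warm-started random-effect mode."""

    def __init__(
        self,
        X: np.ndarray,
        y: np.ndarray,
        m: np.ndarray,
        subj_idx: np.ndarray,
        n_subj: int,
        item_idx: Optional[np.ndarray],
        n_item: int,
        ridge: float = 0.0,
    ):
        self.X, self.y, self.m = X, y, m
        self.subj_idx, self.n_subj = subj_idx, n_subj
        self.item_idx, self.n_item = item_idx, n_item
        self.q = n_subj + (n_item if item_idx is not None else 0)
        self.b = np.zeros(self.q)
        self.ridge = ridge
        self.const = float(
            np.sum(
                special.gammaln(m + 1)
                - special.gammaln(y + 1)
                - special.gammaln(m - y + 1)
            )
        )

    def _eta(self, beta: np.ndarray, b: np.ndarray) -> np.ndarray:
        eta = self.X @ beta + b[self.subj_idx]
        if self.item_idx is not None:
            eta = eta + b[self.n_subj + self.item_idx]
        return eta

    def _zt(self, v: np.ndarray) -> np.ndarray:
        """Z' v for the random-effect design."""
        out = np.zeros(self.q)
        np.add.at(out, self.subj_idx, v)
        if self.item_idx is not None:
            np.add.at(out, self.n_subj + self.item_idx, v)
        return out

    def _ztwz(self, w: np.ndarray) -> np.ndarray:
        H = np.zeros((self.q, self.q))
        ws = np.bincount(self.subj_idx, weights=w, minlength=self.n_subj)
        H[: self.n_subj, : self.n_subj][
            np.diag_indices(self.n_subj)
        ] = ws
        if self.item_idx is not None:
            wi = np.bincount(self.item_idx, weights=w, minlength=self.n_item)
            H[self.n_subj :, self.n_subj :][np.diag_indices(self.n_item)] = wi
            cross = np.zeros((self.n_subj, self.n_item))
            np.add.at(cross, (self.subj_idx, self.item_idx), w)
            H[: self.n_subj, self.n_subj :] = cross
            H[self.n_subj :, : self.n_subj] = cross.T
        return H

    def _dinv(self, sd: np.ndarray) -> np.ndarray:
        out = np.empty(self.q)
        out[: self.n_subj] = 1.0 / sd[0] ** 2
        if self.item_idx is not None:
            out[self.n_subj :] = 1.0 / sd[1] ** 2
        return out

    def laplace_ll(self, beta: np.ndarray, sd: np.ndarray) -> float:
        """Laplace-approximate marginal log-likelihood; updates the cached mode."""
        dinv = self._dinv(sd)
        b = self.b.copy()
        for _ in range(100):
            eta = self._eta(beta, b)
            p = special.expit(eta)
            grad = self._zt(self.y - self.m * p) - dinv * b
            w = self.m * p * (1 - p)
            H = self._ztwz(w)
            H[np.diag_indices(self.q)] += dinv
            try:
                step = np.linalg.solve(H, grad)
            except np.linalg.LinAlgError:
                H[np.diag_indices(self.q)] += 1e-8
                step = np.linalg.solve(H, grad)
            # damped Newton on the penalized joint log-likelihood
            def joint(bb):
                e = self._eta(beta, bb)
                return float(
                    np.sum(self.y * e - self.m * _log1pexp(e))
                    - 0.5 * np.sum(dinv * bb**2)
                )

            f0 = joint(b)
            t = 1.0
            for _ in range(20):
                b_new = b + t * step
                if joint(b_new) >= f0 - 1e-12:
                    break
                t /= 2.0
            b = b_new
            if np.max(np.abs(grad)) < 1e-8:
                break
        self.b = b
        eta = self._eta(beta, b)
        p = special.expit(eta)
        w = self.m * p * (1 - p)
        H = self._ztwz(w)
        H[np.diag_indices(self.q)] += dinv
        sign, logdet_h = np.linalg.slogdet(H)
        if sign <= 0:
            return -np.inf
        logdet_d = float(np.sum(-np.log(dinv)))
        ll = (
            float(np.sum(self.y * eta - self.m * _log1pexp(eta)))
            + self.const
            - 0.5 * float(np.sum(self._dinv(sd) * b**2))
            - 0.5 * logdet_d
            - 0.5 * logdet_h
        )
        if self.ridge > 0:
            ll -= self.ridge * float(np.sum(beta**2))
        return ll


def fit_phase_glmm(
    counts: pd.DataFrame,
    include_age: bool = False,
    random_effects: Sequence[str] = ("subject", "item"),
    standardize_age: bool = True,
) -> GlmmResult:
    """Fit the binomial mixed logit to a phase-count table.

    ``random_effects`` is ("subject", "item") for the nouns design and
    ("subject",) for the honorifics design.  Raises
    :class:`~gazelex.errors.ConvergenceError` on optimizer failure; emits a
    warning and refits with a small ridge penalty when the data are separated
    (some factor level all-target or all-distractor).
    """
    if counts.empty:
        raise GazelexError("no binomial observations to fit")
    if "subject" not in random_effects:
        raise GazelexError("the model requires at least a subject random intercept")
    use_item = "item" in random_effects

    X, terms = _design(counts, include_age, standardize_age)
    y = counts["n_target"].to_numpy(dtype=float)
    m = (counts["n_target"] + counts["n_distractor"]).to_numpy(dtype=float)
    subj_codes, subj_levels = pd.factorize(counts["subject_id"], sort=True)
    if use_item:
        item_codes, item_levels = pd.factorize(counts["item_id"], sort=True)
    else:
        item_codes, item_levels = None, []

    result = _fit(X, terms, y, m, subj_codes, list(subj_levels), item_codes,
                  list(item_levels), ridge=0.0)
    if not np.all(np.isfinite(result.coef)) or np.any(np.abs(result.coef) > 15):
        warnings.warn(
            "possible separation in the phase counts; refitting with a weak "
            "ridge penalty on the fixed effects"
        )
        result = _fit(X, terms, y, m, subj_codes, list(subj_levels), item_codes,
                      list(item_levels), ridge=1e-2)
    return result


def _fit(X, terms, y, m, subj_idx, subj_levels, item_idx, item_levels, ridge) -> GlmmResult:
    n_subj, n_item = len(subj_levels), len(item_levels)
    prob = _LaplaceProblem(X, y, m, subj_idx, n_subj, item_idx, n_item, ridge)
    k = X.shape[1]
    n_sd = 2 if item_idx is not None else 1

    # moment-based starting values
    p0 = np.clip((y.sum() + 0.5) / (m.sum() + 1.0), 1e-3, 1 - 1e-3)
    x0 = np.concatenate([[np.log(p0 / (1 - p0))], np.zeros(k - 1), np.full(n_sd, np.log(0.3))])

    def objective(params):
        beta = params[:k]
        sd = np.exp(np.clip(params[k:], -6.0, 3.0))
        return -prob.laplace_ll(beta, sd)

    res = optimize.minimize(
        objective,
        x0,
        method="Nelder-Mead",
        options={"xatol": 1e-5, "fatol": 1e-7, "maxiter": 4000, "maxfev": 6000},
    )
    if not res.success:
        raise ConvergenceError("GLMM optimizer failed to converge", trace=res)
    beta = res.x[:k]
    sd = np.exp(np.clip(res.x[k:], -6.0, 3.0))
    ll = prob.laplace_ll(beta, sd)  # refresh the cached random-effect mode
    b_hat = prob.b.copy()
    ranef_subject = dict(zip([str(s) for s in subj_levels], b_hat[:n_subj]))
    ranef_item = (
        dict(zip([str(s) for s in item_levels], b_hat[n_subj:]))
        if item_idx is not None
        else None
    )

    # Wald covariance: observed information of the Laplace log-likelihood in
    # the fixed effects, holding variance components at their estimates
    H = np.zeros((k, k))
    h = 1e-4 * np.maximum(np.abs(beta), 1.0)
    for a in range(k):
        for b_ in range(a, k):
            ea = np.zeros(k)
            eb = np.zeros(k)
            ea[a] = h[a]
            eb[b_] = h[b_]
            val = -(
                prob.laplace_ll(beta + ea + eb, sd)
                - prob.laplace_ll(beta + ea - eb, sd)
                - prob.laplace_ll(beta - ea + eb, sd)
                + prob.laplace_ll(beta - ea - eb, sd)
            ) / (4 * h[a] * h[b_])
            H[a, b_] = H[b_, a] = val
    try:
        cov = np.linalg.inv(H)
        se = np.sqrt(np.clip(np.diag(cov), 0, None))
    except np.linalg.LinAlgError:
        se = np.full(k, np.nan)

    z = sps.norm.ppf(0.975)
    wald = (beta / se) ** 2
    return GlmmResult(
        terms=terms,
        coef=beta,
        se=se,
        odds_ratios=np.exp(beta),
        or_ci_low=np.exp(beta - z * se),
        or_ci_high=np.exp(beta + z * se),
        wald_chisq=wald,
        wald_p=sps.chi2.sf(wald, 1),
        subject_sd=float(sd[0]),
        item_sd=float(sd[1]) if item_idx is not None else None,
        loglik=float(ll),
        n_obs=len(y),
        n_params=k + n_sd,
        converged=bool(res.success),
        message=str(res.message),
        ranef_subject=ranef_subject,
        ranef_item=ranef_item,
    )


def compare_models(null: GlmmResult, full: GlmmResult) -> tuple[float, int, float]:
    """Likelihood-ratio test of nested Laplace fits: (chisq, df, p)."""
    if null.n_obs != full.n_obs:
        raise GazelexError("LRT requires both models fit to identical data")
    if not set(null.terms) <= set(full.terms):
        raise GazelexError(
            f"models are not nested: {null.terms} vs {full.terms}"
        )
    df = full.n_params - null.n_params
    if df < 0:
        raise GazelexError("null model has more parameters than the full model")
    chisq = max(0.0, 2.0 * (full.loglik - null.loglik))
    p = float(sps.chi2.sf(chisq, df)) if df > 0 else 1.0
    return chisq, df, p


def logit_or_to_cohens_d(odds_ratio: float) -> float:
    """Standard logistic conversion d = ln(OR) * sqrt(3) / pi."""
    return float(np.log(odds_ratio) * np.sqrt(3.0) / np.pi)
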