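"""Bootstrap, nonparametric tests, effect sizes, and the intercept LMM."""

import itertools

import numpy as np
import pandas as pd
import pytest

from gazelex.errors import GazelexError
from gazelex.stats import (
    bootstrap_item_grand_mean,
    exact_sign_test,
    fit_intercept_lmm,
    kendall_tau,
    one_sample_cohens_d,
    percentile_bootstrap_ci,
    wilcoxon_signed_rank,
)


def enumerate_sign_test(n_pos, n_total):
    """Exact two-sided binomial p by full enumeration (minimum-likelihood rule)."""
    from math import comb

    pmf = [comb(n_total, k) * 0.5**n_total for k in range(n_total + 1)]
    obs = pmf[n_pos]
    return sum(p for p in pmf if p <= obs * (1 + 1e-12))


def enumerate_wilcoxon(values):
    """Exact two-sided signed-rank p by enumerating all 2^n sign patterns."""
    from scipy.stats import rankdata

    values = np.asarray(values, dtype=float)
    values = values[values != 0]
    n = len(values)
    ranks = rankdata(np.abs(values))
    w_obs = ranks[values > 0].sum()
    ws = []
    for signs in itertools.product([0, 1], repeat=n):
        ws.append(sum(r for s, r in zip(signs, ranks) if s))
    ws = np.asarray(ws)
    p_le = np.mean(ws <= w_obs + 1e-9)
    p_ge = np.mean(ws >= w_obs - 1e-9)
    return min(1.0, 2 * min(p_le, p_ge))


class TestBootstrap:
    def test_constant_vector_degenerate_with_warning(self):
        with pytest.warns(UserWarning, match="degenerate"):
            res = percentile_bootstrap_ci([0.5] * 8, n_reps=1000, seed=0)
        assert res.ci_low == res.ci_high == 0.5

    def test_reproducible_under_fixed_seed(self, rng):
        data = rng.normal(0.12, 0.07, size=8)
        a = percentile_bootstrap_ci(data, n_reps=2000, seed=42)
        b = percentile_bootstrap_ci(data, n_reps=2000, seed=42)
        assert (a.ci_low, a.ci_high) == (b.ci_low, b.ci_high)

    def test_coverage_near_nominal(self, rng):
        """~95% of CIs on N(0.12, 0.07^2), n=8 samples cover the true mean."""
        hits = 0
        n_sim = 400
        for _ in range(n_sim):
            data = rng.normal(0.12, 0.07, size=8)
            res = percentile_bootstrap_ci(data, n_reps=1000, seed=int(rng.integers(2**31)))
            hits += res.ci_low <= 0.12 <= res.ci_high
        # percentile bootstrap at n=8 undercovers slightly; allow a wide band
        assert 0.82 <= hits / n_sim <= 0.99

    def test_width_shrinks_like_root_n(self, rng):
        widths = []
        for n in (20, 80, 320):
            data = rng.normal(0, 1, size=n)
            res = percentile_bootstrap_ci(data, n_reps=3000, seed=7)
            widths.append(res.ci_high - res.ci_low)
        assert widths[0] > widths[1] > widths[2]
        # quadrupling n should roughly halve the width
        assert widths[2] < widths[0] / 2.5

    def test_item_grand_mean_bootstrap_matches_point_estimate(self, rng):
        rows = pd.DataFrame(
            {
                "subject_id": np.repeat([f"s{k}" for k in range(10)], 4),
                "word_pair_id": list("abcd") * 10,
                "score": rng.uniform(-0.2, 0.6, size=40),
            }
        )
        res = bootstrap_item_grand_mean(rows, n_reps=2000, seed=3)
        expected = rows.groupby("word_pair_id")["score"].mean().mean()
        assert res.estimate == pytest.approx(expected)
        assert res.ci_low <= res.estimate <= res.ci_high


class TestWilcoxon:
    def test_all_positive_n8(self):
        res = wilcoxon_signed_rank([1, 2, 3, 4, 5, 6, 7, 8])
        assert res.p_value == pytest.approx(2 / 2**8)

    def test_antisymmetric_pair(self):
        res = wilcoxon_signed_rank([-3.0, 3.0])
        assert res.p_value == pytest.approx(1.0)

    def test_zeros_dropped(self):
        a = wilcoxon_signed_rank([0.0, 1.0, 2.0, 3.0])
        b = wilcoxon_signed_rank([1.0, 2.0, 3.0])
        assert a.p_value == b.p_value
        assert a.n == 3

    def test_exact_matches_enumeration_oracle(self, rng):
        for n in range(2, 13):
            values = rng.normal(0.3, 1.0, size=n)
            values = values[values != 0]
            if len(values) < 2 or len(np.unique(np.abs(values))) < len(values):
                continue
            res = wilcoxon_signed_rank(values)
            assert res.p_value == pytest.approx(enumerate_wilcoxon(values), abs=1e-12)

    def test_large_sample_approximation_close_to_exact(self, rng):
        from scipy import stats as sps

        values = rng.normal(0.4, 1.0, size=30)
        approx = wilcoxon_signed_rank(values).p_value
        exact = sps.wilcoxon(values, alternative="two-sided", method="exact").pvalue
        assert approx == pytest.approx(exact, abs=0.01)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(GazelexError):
            wilcoxon_signed_rank([0.0, 0.0, 0.0])


class TestSignTest:
    def test_two_of_two(self):
        assert exact_sign_test(2, 2).p_value == pytest.approx(0.5)

    def test_eleven_of_fifteen(self):
        assert exact_sign_test(11, 15).p_value == pytest.approx(0.118, abs=5e-4)

    def test_eight_of_eight(self):
        assert exact_sign_test(8, 8).p_value == pytest.approx(2 * 0.5**8)

    def test_matches_enumeration_for_all_small_n(self):
        for n in range(1, 21):
            for k in range(n + 1):
                assert exact_sign_test(k, n).p_value == pytest.approx(
                    enumerate_sign_test(k, n), abs=1e-12
                )

    def test_empty_rejected(self):
        with pytest.raises(GazelexError):
            exact_sign_test(0, 0)


class TestCohensD:
    def test_hand_computed_pair(self):
        assert one_sample_cohens_d([0.08, 0.18]) == pytest.approx(1.8385, abs=1e-4)

    def test_zero_mean(self):
        assert one_sample_cohens_d([-0.3, 0.3]) == 0.0

    def test_scale_invariance(self, rng):
        x = rng.normal(0.5, 1.0, size=20)
        assert one_sample_cohens_d(3.7 * x) == pytest.approx(one_sample_cohens_d(x))


class TestKendall:
    def test_perfect_concordance(self):
        assert kendall_tau([1, 2, 3, 4], [10, 20, 30, 40]).statistic == pytest.approx(1.0)

    def test_single_discordant_pair(self):
        assert kendall_tau([1, 2, 3], [1, 3, 2]).statistic == pytest.approx(1 / 3)

    def test_symmetry(self, rng):
        x = rng.normal(size=15)
        y = rng.normal(size=15)
        assert kendall_tau(x, y).statistic == pytest.approx(kendall_tau(y, x).statistic)

    def test_constant_vector_rejected(self):
        with pytest.raises(GazelexError):
            kendall_tau([1, 1, 1], [1, 2, 3])


def _score_frame(rng, n_subj=21, n_pairs=8, mean=0.12, subj_sd=0.14, resid_sd=0.10):
    subj = np.repeat([f"s{k:02d}" for k in range(n_subj)], n_pairs)
    b = np.repeat(rng.normal(0, subj_sd, size=n_subj), n_pairs)
    y = mean + b + rng.normal(0, resid_sd, size=n_subj * n_pairs)
    return pd.DataFrame(
        {"subject_id": subj, "word_pair_id": list(range(n_pairs)) * n_subj, "score": y}
    )


class TestInterceptLmm:
    def test_balanced_intercept_equals_grand_mean(self, rng):
        df = _score_frame(rng)
        res = fit_intercept_lmm(df)
        # with balanced cluster sizes the GLS mean is the grand mean exactly
        assert res.intercept == pytest.approx(df["score"].mean(), abs=1e-9)

    def test_null_recovery(self, rng):
        df = _score_frame(rng, mean=0.0)
        res = fit_intercept_lmm(df)
        assert abs(res.intercept) < 3 * res.intercept_se

    def test_satterthwaite_df_in_valid_range(self, rng):
        df = _score_frame(rng)
        res = fit_intercept_lmm(df)
        assert 1.0 < res.df <= len(df) - 1
        # substantial subject variance puts df near the subject count
        assert res.df < 2.5 * 21

    def test_matches_statsmodels_reml(self, rng):
        import statsmodels.formula.api as smf

        df = _score_frame(rng)
        mine = fit_intercept_lmm(df)
        sm_fit = smf.mixedlm("score ~ 1", df, groups=df["subject_id"]).fit(reml=True)
        assert mine.intercept == pytest.approx(sm_fit.params["Intercept"], abs=1e-5)
        assert mine.intercept_se == pytest.approx(sm_fit.bse["Intercept"], rel=1e-3)
        assert mine.subject_var == pytest.approx(float(sm_fit.cov_re.iloc[0, 0]), rel=2e-2, abs=1e-5)
        assert mine.residual_var == pytest.approx(sm_fit.scale, rel=2e-2)

    def test_lrt_nonnegative_and_detects_signal(self, rng):
        df = _score_frame(rng, mean=0.15)
        res = fit_intercept_lmm(df)
        assert res.lrt_chisq >= 0
        assert res.lrt_p < 0.05

    def test_interval_coverage_on_recovery_grid(self, rng):
        """~95% of Satterthwaite intervals cover the generating mean."""
        hits = 0
        n_sim = 120
        for _ in range(n_sim):
            df = _score_frame(
                rng, mean=0.12, subj_sd=np.sqrt(0.02), resid_sd=np.sqrt(0.01)
            )
            res = fit_intercept_lmm(df)
            hits += res.ci_low <= 0.12 <= res.ci_high
        assert 0.88 <= hits / n_sim <= 1.0
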