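# Methods

## Data model and timing conventions

A session is one infant's visit: a trial manifest (word-pair, image-pair
index, target word, target side, target-word onset on the session clock,
contamination flags) plus interval-coded looks (LEFT/RIGHT/AWAY with
half-open spans `[onset, offset)` in integer milliseconds). Manual coding
from 60 FPS video cannot resolve below ~17 ms, so integer milliseconds lose
nothing. Gaps between coded looks are treated as away-looking rather than
interpolated: coders mark visible fixations only, so uncoded time is by
construction off-display. Looks within a trial must not overlap; overlap is
a coding error and is rejected at read time with the offending trial named.

All analysis windows are half-open and expressed relative to target-word
onset after alignment: pre-naming `[0, 367)` ms (the saccade-programming
latency during which gaze cannot yet reflect the word) and the analysis
window `[367, 3500)` ms. Looks spanning a boundary are clipped by the
summarizer, not split at alignment.

## Exclusion rules

Per trial, all applicable reasons are recorded (they frequently co-occur):

* `NO_PRENAMING_LOOK` — zero on-display time anywhere in `[0, 367)`. A look
  that begins before onset and continues into the window counts: it overlaps
  the window, so the infant was demonstrably on-display.
* `CRYING`, `ADULT_ERROR` — manifest flags, taken at face value.
* `MIN_LOOKING` — on-display time in the analysis window strictly below one
  third of it. The boundary 3133/3 ms is not representable in binary floating
  point, so the comparison is kept exact as `3·looking < 3133`.

Subjects are retained when usable trials reach at least half the *designed*
trial count (16 of 32, or 4 of 8) — designed, not attempted, since an
unattempted trial is still a failure to contribute usable data. The boundary
is inclusive ("at least half").

## The difference score

Looking proportions use on-display time only: `p = target / (target +
distractor)`. Away time is excluded from the denominator; besides being the
convention for this paradigm, it makes the image-designation symmetry exact
(`score = p₁ + p₂ − 1` from either image's point of view), which the test
suite checks to 1e-12. An image-pair score exists only when both
presentations are usable; a word-pair score is the mean of its 1 or 2
complete image-pairs (a single complete image-pair is used alone rather than
discarded — requiring both would be stricter than the rule the score needs).
A subject with no complete image-pair for a word-pair is missing for that
pair, never zero. Item means average over subjects with a defined score;
subject means over the subject's defined pairs; both marginals recompute
exactly from the score table by group-by.

Zero on-display time in the analysis window makes the proportion undefined
and raises an error rather than returning NaN — such a trial always fails
the one-third rule, so reaching that state means exclusions were skipped.

## Binning

The binomial response of the phase model is the count of 20 ms bins on the
target vs. the distractor, per trial and phase. Bin `k` covers
`[start + k·20, start + (k+1)·20)`; a trailing partial bin is dropped (156
analysis bins, 18 pre-naming bins). Each bin takes the role occupying the
majority of it; ties break toward the role active at the bin's first
instant, then by TARGET > DISTRACTOR > AWAY. Majority labeling is the least
biased single-label reduction, and at 1 ms bins the label counts equal the
role durations exactly (a test asserts this). Bins are counted from the
window edge (367 ms), not from a grid anchored at 0; anchoring is a
windowing choice, not a data property, and the window-edge convention keeps
pre-naming and analysis series independent of each other's length.

## Inference on scores

* **Bootstrap**: percentile intervals, 10,000 replicates by default, seeded.
  Subjects are the exchangeable unit everywhere: subject-level and grand
  means resample subjects; the item-level grand mean resamples subjects and
  recomputes item means within each replicate.
* **Wilcoxon signed-rank**: two-sided, zeros dropped; exact null by
  enumeration for n ≤ 25 (untied ranks), else normal approximation with
  continuity correction.
* **Exact sign test**: two-sided binomial at p₀ = 1/2 with the
  minimum-likelihood rule (sum of outcome probabilities no greater than the
  observed outcome's).
* **Cohen's d**: mean over the n−1 sample standard deviation.
* **Kendall τ**: tau-b, two-sided.
* **Random-intercept LMM** `score ~ 1 + (1 | subject)`: REML via the
  closed-form marginal likelihood of the compound-symmetric model (per-subject
  means and sums of squares are sufficient); variance components optimized on
  the log scale by Nelder–Mead. The t statistic uses Satterthwaite degrees of
  freedom — `df = 2·Var(μ̂)² / Var(Var(μ̂))` with the variance-of-variance
  from the inverse observed REML information (finite differences) — clamped
  to `[1, N−1]`, falling back to `n_subjects − 1` if the information matrix
  is singular (variance on the boundary). The intercept LRT refits both the
  full and the zero-mean null model by maximum likelihood. statsmodels
  MixedLM is the cross-check oracle in the tests, not the fitting engine,
  because it exposes neither Satterthwaite df nor this LRT.

All tests are two-sided throughout; one-sidedness was never stated for any
of them and two-sided is the conservative default.

## The binomial mixed logit

Fixed effects: intercept and phase (reference: pre-naming), optionally
standardized age and phase×age. Age is z-scored over subjects (not over
rows) so that heavy lookers do not shift the age scale; raw months are
available by flag. Random intercepts: subject and item (word-pair) for the
32-trial nouns design; subject only for the honorifics design, whose two
items cannot support an item variance.

The marginal likelihood is maximized under the Laplace approximation: an
inner damped Newton solve for the random-effect mode (crossed
subject × item structure, dense q×q system, gradient tolerance 1e-8), an
outer Nelder–Mead over fixed effects and log standard deviations. Wald
covariance is the inverse observed information of the Laplace log-likelihood
in the fixed effects, holding variance components at their estimates; odds
ratios are exponentiated coefficients with normal-theory CIs, and the Wald
χ² is `(coef/SE)²`. Nested fits are compared by `2·Δloglik` with df = the
parameter-count difference. Tests verify the Laplace fit against an
adaptive Gauss–Hermite quadrature oracle (agreement within 0.01 on the
logit scale for subject-only models) and against plain logistic regression
in the degenerate single-cluster case. Complete separation (a level with
all-target or all-distractor bins) triggers a warning and a refit with a
weak ridge (1e-2) on the fixed effects.

## Timecourse

At each 33 ms interval of `[−1000, 3500)` ms, every usable trial contributes
its majority state; the plotted proportion is pooled target contributions
over pooled on-display contributions, with a by-subject bootstrap CI (each
resampled subject carries all its trials). Pooling over trials (rather than
averaging subjects first) is the common convention and the default; the
per-subject counts are computed separately internally, so the alternative is
a one-line change. The overlay is a weighted local quadratic regression:
tricube distance weights times the per-point on-display count, span 0.25 of
the defined points (span and degree are conventions, not recoverable from
any source; they are configurable). statsmodels' lowess supports neither
weights nor local quadratics, hence the small in-house smoother.

## The synthetic gaze process

Per trial, gaze over `[−1000, 3500)` ms is a first-order Markov chain on a
20 ms grid over {TARGET, DISTRACTOR, AWAY}: with probability `stay_prob`
the state persists; otherwise it redraws — AWAY with probability
`away_prob`, else TARGET with probability `logistic(η)`. Because the redraw
distribution is also the chain's stationary distribution, the marginal
per-bin odds of target looking are exactly `e^η` at any persistence, so the
generator's effects are on the same logit scale the model estimates.
Persistence is deliberate: real gaze is strongly autocorrelated, and
independent bins would make the binomial working assumption of the phase
model trivially true and its tests uninformative.

η is the baseline image-preference difference before 367 ms post-onset, and
adds the knowledge effect, subject and item effects, and the age slope from
367 ms on — the effect switches at the analysis-window boundary so that the
simulation truth aligns with the analysis contrast. Runs of on-display bins
are merged into look records; away runs become gaps. Crying and
experimenter-error flags are per-trial Bernoulli draws. One integer seed
drives everything; identical seeds give byte-identical study files.

Defaults and why:

| parameter | default | rationale |
| --- | --- | --- |
| `n_subjects` | 21 | the field cohort size |
| `age_range_months` | 5.3–15.4 | the field cohort's age span (uniform) |
| `knowledge_effect` | 0.25 | logit shift giving a phase OR ≈ 1.28 |
| `age_slope` | 0.08 | logit per SD of age, OR ≈ 1.08 |
| `subject_effect_sd` / `item_effect_sd` | 0.3 / 0.2 | moderate heterogeneity: subject spread exceeds item spread, both small against the effect scale |
| `baseline_image_pref_sd` | 0.3 | visible but not dominant baseline preferences (per-image logit offsets) |
| `away_prob` | 0.25 | ~75% on-display time, typical for attentive infant trials |
| `stay_prob` | 0.9 | mean state run ≈ 200 ms before a redraw (which often repeats the state), giving fixation-scale persistence |
| `crying_prob` / `error_prob` | 0.05 / 0.03 | together with away-driven under-looking, mid-teens percent trial exclusion |

What the generator does **not** emulate: saccade latencies and
onset-contingent dynamics (the post-naming shift is instantaneous at
367 ms), incremental word recognition within the window, trial-order
fatigue, or coder disagreement. Consequently, passing recovery tests shows
that the pipeline measures what this process generates on the right scale —
not that the process is a complete model of infant gaze.

Two modeling mismatches are intentional and documented: (i) subject and
item effects enter post-naming only, while the fitted model's random
intercepts span both phases — with mean-zero effects this leaves the phase
coefficient approximately unbiased, and the recovery tolerance (|bias| <
0.03 on the logit scale over 200 cohorts) absorbs the residual logit-pooling
attenuation from unmodeled trial-level preference heterogeneity; (ii) the
persistence default violates conditional bin independence, inflating the
sampling variance of the phase coefficient well beyond its model-based Wald
SE. CI-coverage calibration therefore uses data simulated from the binomial
mixed logit itself (independent bins given η), where nominal 95% coverage
is the correct expectation; under the persistent process, model-based
intervals are anti-conservative by design of the check, not by accident.

## Problem sizes in the test suite

The parameter-recovery and coverage studies use 200 replicates of the
21-subject design — enough for a Monte-Carlo SE of ~0.008 on the bias (vs.
the 0.03 tolerance) and ~1.5% on coverage. Bootstrap unit tests use 1,000 to
3,000 replicates; the pipeline default stays at 10,000.

## Known limitations

* The Laplace approximation is accurate here because each observation is a
  binomial with 18 or 156 trials; for sparse designs (few bins per phase)
  adaptive quadrature would be preferable for subject-only models.
* The minimum-looking and prenaming rules assume the manifest's target-onset
  time is trustworthy; no audio re-alignment is attempted.
* The effect-size conversion `d = ln(OR)·√3/π` is provided alongside the
  mean/SD Cohen's d; the two answer different questions and are not
  interchangeable.
* Reaction-time / first-shift analyses, growth-curve models, and
  cluster-based permutation tests over the timecourse are out of scope.
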