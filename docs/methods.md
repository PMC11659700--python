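# Methods

`sitraj` analyzes per-user daily risk-score time series derived from
social-media text against external survey measures of suicidal ideation
(SI), and quantifies how responses to public suicidal mentions relate to
the poster's subsequent risk trajectory.  This note documents the models,
the synthetic data the package is validated on, and the numerical and
design choices a maintainer would want to know about.

## Scoring model and daily aggregation

The unit of observation is a post.  A *risk scorer* maps one text to a
score in [0, 1], higher meaning higher indicated risk of SI.  The scorer
is a pluggable contract (`scoring.RiskScorer`); two implementations ship:

- `LexiconRiskScorer` — a Laplace-smoothed hit-rate ratio over a
  risk/protective word-list pair, `(r + 0.5) / (r + p + 1)`.  Transparent
  and stateless; it is the scorer used throughout the synthetic studies,
  where the generating lexicons are known.
- `reference_scorer_fit` — the construct-lexicon design used by published
  text-to-risk models: each post becomes a vector of normalized hit rates
  over named psychological-construct lexicons (depression, hopelessness,
  loneliness, ...), and a random forest trained on case/control posts
  outputs a case probability.  This is a reference implementation of the
  design, not a reproduction of any published model's training corpus or
  performance.

Post scores are averaged within UTC calendar days (user time zones are
unknown in this kind of data, so UTC is the only defensible boundary) to
give the *mean daily score* `S̄_u(d)` and post count `n_u(d)`.  Days
without posts are absent, never imputed to zero; explicit gap filling is
available only through the forecasting module and flags its output.
Posts are equally weighted within a day; whether a per-day cap would be
preferable is unknowable without the source data.

*Windowed means*: the mean of daily scores over the D days strictly
before an anchor (survey) day, restricted to days with at least
`max(1, min_posts_per_day)` posts.  "One day before survey completion"
therefore equals `window_days=1`; a flag includes the anchor day itself.
An empty window is a missing value that propagates — never a silent zero.

## Association of scores with survey SI

SI is a single ordinal item (0–3) from a depression inventory (BDI item 9
or QIDS-SR16 item 12, both referencing the prior seven days), used
quantitatively.  The central regression is

    si ~ mean_score + mean_posts + mean_score : mean_posts (+ covariates)

fit per window length over a sliding family of windows anchored at each
survey day.  The interaction term carries the substantive claim: scores
estimated from more posts are more reliable, so the association of score
with SI strengthens with posting volume.  Two p-values are kept per fit:
the overall F-test p (the figure printed next to F statistics in this
literature) and the two-tailed test of the interaction coefficient, which
is what the −ln p scan trace plots.  The default model has exactly the
three slope terms; declared covariates (stress, anxiety, depression) are
optional additions.  No multiplicity correction is applied across windows
by default; a Benjamini–Hochberg flag exists.

Robust fits use iteratively reweighted least squares with Huber weights
(tuning constant 1.345, the textbook 95%-efficiency value).  Routing
between parametric and nonparametric/robust branches goes through an
Anderson–Darling normality gate (case 3: estimated mean and variance,
small-sample-corrected A², tabulated critical values; constant samples
route nonparametric).  Covariate correction (`regress_out`) retains
residuals of the outcome on covariates plus intercept; the literal
"subtract the residuals" reading (which would leave the fitted values) is
available behind `keep="fitted_removed"` for comparison only.

Binary discrimination (SI at or above a threshold) is summarized by the
AUC computed as the Mann–Whitney pair statistic from midranks, with
significance from Monte-Carlo label permutation (default 10,000
permutations).  Because ranks are fixed under relabeling, the null AUCs
are computed by permuting the case index set only — exact and fast.  The
add-one estimator `(1 + #{AUC* ≥ AUC}) / (n_perm + 1)` avoids zero
p-values.

## Within-person slope coupling

For each successive pair of a user's survey entries, the SI change per
day is paired with the score change per day.  The score slope is either
the least-squares slope over every scored day in the closed inter-survey
interval (`all_days_between`; endpoints included because survey-day posts
are informative) or the difference quotient of the two entry days
(`entry_days_only`).  The interaction model

    si_slope ~ score_slope + delta_days + score_slope : delta_days

asks whether the gap between surveys moderates the coupling; with
`method="auto"`, OLS residuals failing the normality gate reroute the fit
to the Huber robust estimator.  The gap-threshold scan computes the
Spearman correlation of the two slopes over pairs with gaps ≤ T for T
from 10 to 100 days; coupling is expected to concentrate at short gaps
because long intervals hide unmeasured excursions of the latent state.

Spearman correlations use average ranks for ties; p-values use the t
approximation for n ≥ 10 and exact enumeration of all n! permutations
below (vectorized; ~0.1 s at n = 9).

## Next-day forecasting ensemble

Per user, linear support-vector regressors are trained on lagged windows
of the daily series, the target being the next day's mean.  Window
lengths start at 14 days and step by 7 until the first length reaching or
exceeding half the user's day span (inclusive), so 100 available days
give windows 14, 21, ..., 56.  Training examples stride by one day and
require complete coverage of the lag vector and target; windows with no
complete example are dropped with a warning.  A forecast is the
equal-weight mean of all windows whose lag days are fully observed,
clipped to [0, 1]; "stacking" here means prediction averaging, not a
learned meta-model, and no window ever sees data on or after the target
day.

Hyperparameters are fixed rather than tuned (C = 1.0, epsilon = 0,
iteration cap 20,000): with dozens of small models per user, a held-out
comparison against realized next-day values is the honest validation
strategy.  Two numerical choices matter and were made deliberately:

- **Epsilon = 0.** With an insensitivity tube of width ε, any constant
  prediction within ±ε of a constant series is loss-optimal, so the
  solver parks anywhere in the tube (measured: exactly ε off).  Epsilon
  zero restores the exact constant-series fixed point.
- **L2-loss SVR in the primal on centered features.**  The dual L1
  (epsilon-insensitive) solver regularizes the intercept toward zero — a
  real bias when scores center near 0.5 — and converges poorly on the
  longest windows, where lag features approach the number of training
  positions.  The squared-epsilon-insensitive variant solved in the
  primal on mean-centered features is numerically stable there; the
  centering is folded back into an affine (weights, bias) form, so
  serialized models are plain dot products.  One consequence: ridge-style
  shrinkage makes extrapolation slightly conservative — a noiseless
  linear trend is tracked within 0.01 on the unit score scale rather
  than interpolated exactly.

`fill_gaps` extends the ensemble to interior missing days by recursive
one-day-ahead forecasting over observed-plus-previously-filled values.
It is a convenience, not a validated imputation method: filled rows carry
an `imputed` flag and `post_count` 0, and days whose lag windows cannot
be completed stay missing.

## Responses to suicidal mentions

A mention event holds the mention timestamp, responses, and the poster's
prior history.  Responses are filtered to the interval (0, 72] hours
after the mention — the boundary is inclusive — excluding retweets and
the poster's own replies.  Per poster, a *positivity model* is built:
history posts are risk-scored, the bottom and top percentile (default
1%, floor of two posts per pole by rank, poles never overlapping) are
labeled 0/1, and a linear SVR on bag-of-words counts is trained on the
extremes.  Lower output means the text resembles the user's most
favorable language.  The tokenizer lowercases, strips URLs and
@-handles, and keeps apostrophized negations ("don't") whole, since such
tokens are meaningful units in the enrichment analysis.

Events are scored as the mean of their response scores (the combiner is
unstated in the literature; the mean is the least-committal choice, and
both event-level and response-level scores are exposed).  The split
threshold defaults to the corpus mean of event scores — published
threshold values are specific to their own corpora — with ties assigned
to the positive group.  Per group, the 21-day post-mention curve of
group-mean daily scores (day 0 = UTC day of the mention) is summarized
by its Spearman correlation with the day index; a pooled user-day
variant is available, but the group-mean curve is the default because
its n matches the reported p magnitudes in this literature.  The final
window (default last 7 of 21 days) is compared between groups with
Student's t or Mann–Whitney U per the normality gate.

## Lexical enrichment

Tokens (words or adjacent bigrams — every quoted example pair in this
literature is an adjacent bigram) are compared between two response
corpora at the level of response presence, not raw frequency, so verbose
responses do not dominate.  Each token appearing at least `min_count`
times (default 5) gets a two-tailed Fisher exact test on its 2×2 presence
table; Fisher is the right test at the corpus sizes typical of response
data (tens to a few hundred responses).  A chi-square variant and a BH
flag exist; no correction by default.  Saturated or empty presence
columns yield odds ratio 1, p = 1, and the row is retained.

## Synthetic cohorts

Every analysis is validated on cohorts from `synthetic` with recorded
ground truth.  The generative model:

- Latent daily distress `z(t) = ρ·z(t−1) + ε(t)` per user, unbounded;
  clipping happens only at the score stage so slope and drift arithmetic
  stays linear.  Defaults ρ = 0.8, ε sd = 0.3 (stationary sd = 0.5):
  distress states persist for days-to-weeks, the regime the windowed
  analyses assume.
- Posting volume Poisson (default 3/day, a moderately active account);
  post score = `clip01(0.5 + 0.15·z + N(0, 0.05))`; post text is a
  word mixture whose risk-vocabulary share equals the true score, so
  lexicon scorers can recover scores from text alone.
- SI at a survey day = number of thresholds below the mean latent state
  over the prior seven days (both inventory items reference the past
  week), with defaults (0.25, 0.75, 1.25) ≈ (0.5, 1.5, 2.5) stationary
  sds — most answers 0, few 3s, matching the low base rates such surveys
  show.  A planted interaction adds
  `interaction_effect × (14-day windowed score × posts/day)` to the
  latent index before thresholding.
- Mention cohorts: the first latent crossing of `mention_threshold` at or
  after a burn-in day becomes one event per user, provided the full
  21-day horizon fits inside the simulated span (no right-censored
  curves).  With probability `response_prob` the event draws 1+Poisson
  responses at times uniform in (0, 72] hours; a planted per-event
  favorability flag selects the response vocabulary (favorable events
  use the user-positive lexicon).  Responded events add `response_drift`
  per day to the latent recursion for 21 days, plus `favorable_drift`
  when the responses are favorable, giving separate ground truth for the
  responded-vs-none and positive-vs-negative contrasts.
- All randomness flows from one root seed via `numpy` `SeedSequence`
  spawning (one child per user, split into latent/posts/survey/mention
  streams), so cohorts are byte-identical across runs and the mention
  machinery never perturbs base trajectories.  `with_texts=False` skips
  text synthesis for score-level studies; it changes the post-stream
  draws and is therefore part of the cohort's identity.

What the generator does **not** emulate: realistic tweet language beyond
lexicon mixtures, follower/network structure, diurnal posting rhythms,
platform dynamics (deletions, virality), or scorer miscalibration.
Passing tests therefore demonstrate that the statistical machinery
recovers known structure under the stated model — not that the pipeline's
conclusions transfer to any real platform.

## Validation studies and their problem sizes

The published coefficient values in this literature derive from private
data and are not reproducible; validation is property-based, with study
sizes chosen to finish in minutes on one CPU:

- **Interaction recovery/calibration**: 500 draws of 300 regression rows
  with a planted interaction of 0.004 (continuous outcome — ordinal
  thresholding attenuates coefficients, so coefficient-scale recovery is
  defined on the continuous index); unbiasedness within 3 Monte-Carlo
  SEs and null rejection in [0.03, 0.07] at α = 0.05.
- **Window localization**: 100 cohorts (500 users, 45 days, surveys at
  days 30, 37 and 44) with `interaction_effect = 1.5` planted through
  the 14-day window (the planted product is centered at the neutral
  score 0.5 so the ordinal item stays off its ceiling); effect size and
  cohort size were fixed by a pre-study power pilot — windows just past
  14 days share most of the planted signal, so the argmin of highly
  correlated p-values needs a large cohort to stabilize.  The scan's
  minimum-p window falls at ≤ 16 days in ≥ 80% of cohorts.
- **Permutation AUC**: Monte-Carlo p within 2 SE of the exhaustive
  20-arrangement p on 3-vs-3 instances; null rejection rate in
  [0.03, 0.07] over 500 replicates at n = 200.
- **Forecast skill**: 200 users of a latent AR(1) (ρ = 0.8, sd 0.3)
  observed 120 days through a noisy daily score (link 0.08, observation
  noise 0.1 — a weak-instrument regime typical of text-derived scores),
  final 10 days held out; the ensemble's MSE beats the last-value
  baseline for ≥ 70% of users (measured ≈ 75%).
- **Positivity recovery and trajectory pattern**: 100 mention cohorts
  with ~50 events per group.  These studies use time-triggered mentions
  (threshold below the latent range): a state-triggered mention selects
  a local maximum of the latent state, and mean reversion alone then
  produces declining curves in *every* group, which is confounded ground
  truth for a drift contrast (the same phenomenon plausibly explains the
  mildly negative no-response trajectories reported on real data).
  Latent noise sd is 0.2 here: at 0.3, 50-member group-mean AR wiggle
  masks a −0.05/day drift.  Checks: text-only group recovery ≥ 90% of
  events, drifting groups decline (ρ < 0, p < .05) in ≥ 80% of sims,
  null groups centered near zero (|mean ρ| < 0.35; they sit slightly
  negative from ~8% assignment contamination by drifting events).
- **Enrichment recovery**: a token planted in 50% vs 5% of 100-response
  corpora is the top-ranked hit in ≥ 95% of simulations.
- **End-to-end**: the shipped demo config (30 users, 100 days) runs all
  seven stages in about a minute and reruns byte-identically.

## Known limitations

- The reference scorer is a design-faithful stand-in; its absolute
  performance is meaningless outside the synthetic corpora.
- Ordinal SI is modeled by thresholding a continuous index; the linear
  models treat it quantitatively, as the analyses they mirror do, so
  coefficients are attenuated relative to the latent scale.
- `fill_gaps` compounds one-step forecasts and inherits their biases;
  it is not a validated imputation procedure.
- The Huber-robust fit reports a normal-approximation p for the
  interaction coefficient and no finite-sample F.
- Event-level and response-level thresholding can disagree for users
  with many responses; the package thresholds event-level means and
  records response-level scores for inspection.
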