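# sitraj

Longitudinal suicide-risk trajectory analytics for social-media
timelines.

People at risk of suicidal ideation (SI) often leave a long, dated trail
of text on social media.  Given a post-level risk scorer — any model
mapping one text to a score in [0, 1], higher meaning higher indicated
risk — `sitraj` turns per-user timelines into mean **daily** risk-score
series and asks the questions a longitudinal risk study asks of them:

- **Association**: does the windowed mean score before a survey day,
  in interaction with posting volume, track the survey's quantitative
  SI item?  (`si ~ S̄ + n + S̄:n`, scanned over window lengths D, with
  AUC + permutation inference for binary thresholds.)
- **Temporal coupling**: within a person, does the slope of daily
  scores between two survey entries track the slope of SI between
  those entries, and over which inter-survey gaps?
- **Forecasting**: can an equal-weight ensemble of linear SVRs on
  14, 21, 28, ... day lag windows predict tomorrow's mean score better
  than carrying today's forward?
- **Responses to suicidal mentions**: after a public suicidal mention,
  do responses within 72 h — and specifically responses scored as
  *personally* favorable by a model trained on the poster's own
  extreme-scoring history — precede an improving 21-day score
  trajectory?  Which words and word pairs are overrepresented in
  favorable vs unfavorable response corpora?

The package is aimed at computational mental-health researchers who
have (or simulate) timeline + survey data.  Real data of this kind is
private, so `sitraj` ships a synthetic-cohort simulator
(`sitraj.synthetic`) with a latent AR(1) distress state, Poisson
posting, ordinal SI read off the past week's latent mean, mention
events with planted response effects, and full ground-truth recording —
every analysis in the package is validated against it.  See
`docs/methods.md` for the model details and design decisions.

## Worked example

Generate a cohort with an association planted only in the 14 days
before each survey, then scan window lengths:

```python
from sitraj.synthetic import CohortConfig, generate_cohort
from sitraj.association import sliding_window_scan

cfg = CohortConfig(
    n_users=500, n_days=45, seed=2000, survey_days=(30, 37, 44),
    interaction_effect=1.5, with_texts=False,
)
cohort = generate_cohort(cfg)
scan = sliding_window_scan(
    cohort.daily_series_by_user(), cohort.all_surveys(), windows=range(1, 31)
)
best = scan.best_window()
fit = scan.fits[best]
print(f"best window  : {best} days (n={fit.n} user-surveys)")
print(f"interaction  : beta={fit.beta_interaction:.3f} (SE {fit.se_interaction:.3f})")
print(f"overall fit  : F({fit.df_num},{fit.df_den})={fit.f_stat:.1f}, p={fit.p_value:.2e}")
print(f"interaction p: {fit.p_interaction:.2e}")
```

prints

```
best window  : 15 days (n=1500 user-surveys)
interaction  : beta=1.835 (SE 0.620)
overall fit  : F(3,1496)=615.9, p=1.26e-260
interaction p: 3.13e-03
```

The scan's most significant window (15 days) sits at the edge of the
14-day band where the effect was planted — windows just past the band
still carry most of the planted signal, so localization to within a
couple of days is the expected resolution.  The interaction coefficient
is positive, as planted (score tracks SI more strongly when estimated
from more posts); `scan.neg_log_p` holds the full −ln p trace by window
length.

## Command line

The same stages run from the shell, reading and writing plain-text
formats (JSONL posts/mentions, CSV surveys/scores):

```bash
sitraj run --config configs/demo.yaml --outdir out/
sitraj associate --outdir out/ --windows 1:21 --min-posts 3
```

`run` executes simulate → score → associate → trajectory → forecast →
respond-score → enrich and writes `manifest.json` with per-stage seeds,
row counts, filter-drop counts, and SHA-256 checksums; rerunning with
the same config reproduces every output byte-for-byte.

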