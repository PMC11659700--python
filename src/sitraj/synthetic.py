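"""Synthetic cohort simulator with recorded ground truth.

The source data for these analyses (social-media timelines paired with
private survey records) cannot be redistributed, so every stage of the
pipeline is exercised against cohorts generated here with known
parameters.  The generative model:

* A latent daily distress state per user follows an AR(1) recursion
  ``z(t) = rho * z(t-1) + eps(t)`` on an unbounded scale (clipping
  happens only at the score stage, keeping slope and drift arithmetic
  linear).
* Posting volume per day is Poisson; each post's true risk score is
  ``clip01(0.5 + score_link_slope * z + noise)`` and its text is a
  word-mixture whose risk-word proportion equals the true score, so
  lexicon scorers can recover scores from text alone.
* Ordinal suicidal-ideation (SI) answers at survey days are the number
  of thresholds lying below the mean latent state over the prior seven
  days — both survey items reference the past week — plus an optional
  planted interaction of the 14-day windowed mean score with posting
  volume.
* Mention cohorts: the first day the latent state crosses a threshold
  (after a burn-in that guarantees trainable history) becomes a
  suicidal-mention event; responses arrive within 72 h with a given
  probability, carry a planted per-event favorability flag driving
  their vocabulary, and responded users' latent state gains a daily
  drift for the following 21 days.

All randomness flows from one root seed through
``numpy.random.SeedSequence`` spawning: one child per user, split again
into latent / posts / survey / mention streams, so cohorts are
byte-identical across runs and mention machinery never perturbs the
base trajectories.
"""

from __future__ import annotations

import dataclasses
import datetime as _dt
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .association import SurveyObservation
from .errors import ConfigurationError
from .positivity import MentionEvent, Response
from .scoring import DailyScoreSeries, Post

__all__ = [
    "CohortConfig",
    "SyntheticUser",
    "SyntheticCohort",
    "generate_cohort",
    "generate_mention_corpus",
    "simulate_interaction_rows",
    "DEFAULT_VOCAB_POS",
    "DEFAULT_VOCAB_NEG",
    "DEFAULT_VOCAB_NEUTRAL",
]

# Favorable-response / low-risk vocabulary (personal, supportive).
DEFAULT_VOCAB_POS = (
    "hope", "love", "care", "proud", "friend", "together", "stay",
    "matter", "worth", "listen", "music", "sunshine", "hiking", "remember", "breathe",
)
# Unfavorable-response / high-risk vocabulary (generic platitudes, hostility).
DEFAULT_VOCAB_NEG = (
    "don't", "do", "it", "please", "everything", "will", "be", "alright",
    "fine", "stop", "drama", "attention", "weak", "whatever", "okay",
)
DEFAULT_VOCAB_NEUTRAL = (
    "the", "a", "to", "and", "of", "in", "on", "for", "with",
    "at", "this", "that", "was", "is", "my",
)


@dataclass(frozen=True)
class CohortConfig:
    """All generative parameters of a synthetic cohort.

    Defaults describe a mid-sized cohort posting a few times a day over
    four months with monthly surveys; see the methods note for the
    reasoning behind each value.
    """

    n_users: int = 150
    n_days: int = 120
    seed: int = 0
    latent_persistence: float = 0.8
    latent_noise_sd: float = 0.3
    post_rate: float = 3.0
    score_link_slope: float = 0.15
    score_noise_sd: float = 0.05
    si_thresholds: tuple[float, float, float] = (0.25, 0.75, 1.25)
    survey_days: tuple[int, ...] | None = None
    interaction_effect: float = 0.0
    interaction_window: int = 14
    si_nest_days: int = 7
    mention_threshold: float = 0.8
    mention_min_day: int = 60
    mention_horizon: int = 21
    response_prob: float = 0.5
    response_drift: float = 0.0
    favorable_drift: float = 0.0
    favorable_prob: float = 0.5
    mean_extra_responses: float = 1.0
    vocab_pos: tuple[str, ...] = DEFAULT_VOCAB_POS
    vocab_neg: tuple[str, ...] = DEFAULT_VOCAB_NEG
    vocab_neutral: tuple[str, ...] = DEFAULT_VOCAB_NEUTRAL
    start_date: _dt.date = _dt.date(2020, 1, 1)
    # Skip word-mixture text synthesis (posts get a placeholder token) for
    # score-level simulation studies that never read text; changes the
    # post-stream RNG consumption, so it is part of the cohort identity.
    with_texts: bool = True

    def __post_init__(self) -> None:
        if self.n_users < 1:
            raise ConfigurationError("n_users must be a positive integer")
        if self.n_days < 1:
            raise ConfigurationError("n_days must be a positive integer")
        if not 0 <= self.latent_persistence < 1:
            raise ConfigurationError("latent_persistence must be in [0, 1)")
        if self.latent_noise_sd < 0:
            raise ConfigurationError("latent_noise_sd must be nonnegative")
        if self.post_rate <= 0:
            raise ConfigurationError("post_rate must be positive")
        if self.score_noise_sd < 0:
            raise ConfigurationError("score_noise_sd must be nonnegative")
        if len(self.si_thresholds) != 3 or not (
            self.si_thresholds[0] < self.si_thresholds[1] < self.si_thresholds[2]
        ):
            raise ConfigurationError("si_thresholds must be 3 strictly increasing reals")
        if self.survey_days is not None and any(
            not 0 <= d < self.n_days for d in self.survey_days
        ):
            raise ConfigurationError("survey_days must lie in [0, n_days)")
        if not 0 <= self.response_prob <= 1:
            raise ConfigurationError("response_prob must be in [0, 1]")
        if not 0 <= self.favorable_prob <= 1:
            raise ConfigurationError("favorable_prob must be in [0, 1]")
        vocabs = [set(self.vocab_pos), set(self.vocab_neg), set(self.vocab_neutral)]
        if any(not v for v in vocabs):
            raise ConfigurationError("vocab_pos/vocab_neg/vocab_neutral must be nonempty")
        if (vocabs[0] & vocabs[1]) or (vocabs[0] & vocabs[2]) or (vocabs[1] & vocabs[2]):
            raise ConfigurationError("vocabularies must be pairwise disjoint")

    @property
    def effective_survey_days(self) -> tuple[int, ...]:
        if self.survey_days is not None:
            return tuple(self.survey_days)
        return tuple(range(28, self.n_days, 28))


@dataclass
class SyntheticUser:
    """One generated user with full ground truth."""

    user_id: str
    scale: str
    latent: np.ndarray = field(repr=False)
    post_days: np.ndarray = field(repr=False)
    posts: list[Post] = field(repr=False)
    true_scores: np.ndarray = field(repr=False)
    surveys: list[SurveyObservation] = field(default_factory=list)
    mention: MentionEvent | None = None
    mention_truth: dict | None = None

    def daily_series(self) -> DailyScoreSeries:
        """Mean daily series from the recorded true post scores."""
        if len(self.posts) == 0:
            return DailyScoreSeries(
                user_id=self.user_id,
                frame=pd.DataFrame(
                    columns=["mean_score", "post_count"], index=pd.Index([], name="date")
                ),
            )
        df = pd.DataFrame({"date": [p.day for p in self.posts], "score": self.true_scores})
        agg = df.groupby("date")["score"].agg(mean_score="mean", post_count="size")
        agg.index.name = "date"
        return DailyScoreSeries(user_id=self.user_id, frame=agg.sort_index())


@dataclass
class SyntheticCohort:
    """Generated users plus the truth record sufficient to regenerate them."""

    config: CohortConfig
    users: list[SyntheticUser]

    @property
    def truth(self) -> dict:
        cfg = dataclasses.asdict(self.config)
        cfg["start_date"] = self.config.start_date.isoformat()
        per_user = {
            u.user_id: {
                "scale": u.scale,
                "mention": u.mention_truth,
            }
            for u in self.users
        }
        return {"config": cfg, "users": per_user}

    def daily_series_by_user(self) -> dict[str, DailyScoreSeries]:
        return {u.user_id: u.daily_series() for u in self.users}

    def all_surveys(self) -> list[SurveyObservation]:
        return [s for u in self.users for s in u.surveys]

    def mention_events(self) -> list[MentionEvent]:
        return [u.mention for u in self.users if u.mention is not None]


def _mixture_text(rng: np.random.Generator, risk_prob: float, cfg: CohortConfig) -> str:
    """Word-mixture text whose risk-vocabulary share equals ``risk_prob``."""
    k = 3 + rng.poisson(5)
    words = []
    for _ in range(k):
        if rng.random() < 0.5:
            words.append(cfg.vocab_neutral[rng.integers(len(cfg.vocab_neutral))])
        elif rng.random() < risk_prob:
            words.append(cfg.vocab_neg[rng.integers(len(cfg.vocab_neg))])
        else:
            words.append(cfg.vocab_pos[rng.integers(len(cfg.vocab_pos))])
    return " ".join(words)


def _response_text(rng: np.random.Generator, favorable: bool, cfg: CohortConfig) -> str:
    k = 3 + rng.poisson(5)
    pool = cfg.vocab_pos if favorable else cfg.vocab_neg
    words = []
    for _ in range(k):
        if rng.random() < 0.3:
            words.append(cfg.vocab_neutral[rng.integers(len(cfg.vocab_neutral))])
        else:
            words.append(pool[rng.integers(len(pool))])
    return " ".join(words)


def _ar1(eps: np.ndarray, rho: float) -> np.ndarray:
    z = np.empty_like(eps)
    z[0] = eps[0]
    for t in range(1, len(eps)):
        z[t] = rho * z[t - 1] + eps[t]
    return z


def _ar1_with_drift(
    eps: np.ndarray, rho: float, start: int, horizon: int, drift: float
) -> np.ndarray:
    """AR(1) where days ``(start, start+horizon]`` gain an additive drift."""
    z = np.empty_like(eps)
    z[0] = eps[0]
    for t in range(1, len(eps)):
        d = drift if start < t <= start + horizon else 0.0
        z[t] = rho * z[t - 1] + eps[t] + d
    return z


def _day_ts(cfg: CohortConfig, day: int, second: float) -> _dt.datetime:
    base = _dt.datetime.combine(cfg.start_date, _dt.time(0, 0), tzinfo=_dt.timezone.utc)
    return base + _dt.timedelta(days=int(day), seconds=float(second))


def _generate(config: CohortConfig, with_mentions: bool) -> SyntheticCohort:
    root = np.random.SeedSequence(config.seed)
    children = root.spawn(config.n_users)
    users: list[SyntheticUser] = []
    survey_days = config.effective_survey_days
    for i, child in enumerate(children):
        s_latent, s_posts, s_survey, s_mention = child.spawn(4)
        rng_l = np.random.default_rng(s_latent)
        rng_p = np.random.default_rng(s_posts)
        rng_s = np.random.default_rng(s_survey)
        rng_m = np.random.default_rng(s_mention)
        uid = f"user{i:04d}"
        scale = "BDI9" if i < config.n_users / 2 else "QIDS12"

        eps = rng_l.normal(0.0, config.latent_noise_sd, config.n_days)
        z = _ar1(eps, config.latent_persistence)
        counts = rng_p.poisson(config.post_rate, config.n_days)

        mention: MentionEvent | None = None
        mention_truth: dict | None = None
        if with_mentions:
            # Only crossings leaving room for the full post-mention horizon
            # become events, so trajectory curves are never right-censored.
            last_ok = config.n_days - config.mention_horizon
            crossing = np.flatnonzero(
                z[config.mention_min_day:last_ok] >= config.mention_threshold
            )
            if crossing.size:
                m_day = int(crossing[0] + config.mention_min_day)
                responded = bool(rng_m.random() < config.response_prob)
                favorable = bool(rng_m.random() < config.favorable_prob)
                drift = 0.0
                if responded:
                    drift = config.response_drift + (
                        config.favorable_drift if favorable else 0.0
                    )
                if drift != 0.0:
                    z = _ar1_with_drift(
                        eps, config.latent_persistence, m_day, config.mention_horizon, drift
                    )
                m_ts = _day_ts(config, m_day, rng_m.uniform(0, 86_400))
                responses: list[Response] = []
                if responded:
                    n_resp = 1 + rng_m.poisson(config.mean_extra_responses)
                    # (0, 72] hours after the mention, inclusive upper bound
                    offsets = (1.0 - rng_m.random(n_resp)) * 72.0
                    for j, off in enumerate(sorted(offsets)):
                        responses.append(
                            Response(
                                ts=m_ts + _dt.timedelta(hours=float(off)),
                                responder_id=f"{uid}-resp{j}",
                                text=_response_text(rng_m, favorable, config),
                            )
                        )
                mention_truth = {
                    "mention_day": m_day,
                    "responded": responded,
                    "favorable": favorable,
                    "drift": drift,
                    "n_responses": len(responses),
                    "response_favorable_flags": [favorable] * len(responses),
                }
                mention = MentionEvent(
                    user_id=uid,
                    mention_ts=m_ts,
                    responses=tuple(responses),
                    history=(),  # attached after posts exist
                    event_id=f"{uid}-m0",
                )

        posts: list[Post] = []
        true_scores: list[float] = []
        post_days: list[int] = []
        daily_sum = np.zeros(config.n_days)
        daily_n = np.zeros(config.n_days, dtype=int)
        for d in range(config.n_days):
            k = int(counts[d])
            if k == 0:
                continue
            seconds = np.sort(rng_p.uniform(0, 86_400, k))
            noise = rng_p.normal(0.0, config.score_noise_sd, k)
            for j in range(k):
                s = float(np.clip(0.5 + config.score_link_slope * z[d] + noise[j], 0.0, 1.0))
                text = _mixture_text(rng_p, s, config) if config.with_texts else "x"
                posts.append(
                    Post(user_id=uid, timestamp=_day_ts(config, d, seconds[j]), text=text)
                )
                true_scores.append(s)
                post_days.append(d)
                daily_sum[d] += s
                daily_n[d] += 1

        surveys: list[SurveyObservation] = []
        for d in survey_days:
            lo = max(0, d - config.si_nest_days)
            nest = z[lo:d]
            nest_mean = float(nest.mean()) if nest.size else float(z[0])
            index = nest_mean
            if config.interaction_effect != 0.0:
                w_lo = max(0, d - config.interaction_window)
                mask = daily_n[w_lo:d] > 0
                if mask.any():
                    w_score = float(
                        (daily_sum[w_lo:d][mask] / daily_n[w_lo:d][mask]).mean()
                    )
                    w_posts = float(daily_n[w_lo:d][mask].mean())
                    # score centered at its neutral 0.5 so the planted term
                    # has near-zero mean and the ordinal item stays off its
                    # ceiling (an uncentered product shifts everyone past
                    # the top threshold and saturation flips the fitted sign)
                    index = nest_mean + config.interaction_effect * (w_score - 0.5) * w_posts
            si = int(np.sum(index > np.asarray(config.si_thresholds)))
            covs = {
                "stress": float(np.clip(13 + 6 * nest_mean + rng_s.normal(0, 4), 0, 40)),
                "anxiety": float(np.clip(5 + 4 * nest_mean + rng_s.normal(0, 3), 0, 21)),
                "depression": float(np.clip(8 + 5 * nest_mean + rng_s.normal(0, 4), 0, 27)),
            }
            surveys.append(
                SurveyObservation(
                    user_id=uid,
                    date=config.start_date + _dt.timedelta(days=int(d)),
                    si=si,
                    scale=scale,
                    covariates=covs,
                )
            )

        if mention is not None:
            history = tuple(p for p in posts if p.timestamp < mention.mention_ts)
            mention = dataclasses.replace(mention, history=history)

        users.append(
            SyntheticUser(
                user_id=uid,
                scale=scale,
                latent=z,
                post_days=np.asarray(post_days),
                posts=posts,
                true_scores=np.asarray(true_scores),
                surveys=surveys,
                mention=mention,
                mention_truth=mention_truth,
            )
        )
    return SyntheticCohort(config=config, users=users)


def generate_cohort(config: CohortConfig) -> SyntheticCohort:
    """Generate a survey cohort (no mention events).

    Deterministic given ``config.seed``; see the module docstring for
    the generative model.
    """
    return _generate(config, with_mentions=False)


def generate_mention_corpus(config: CohortConfig) -> SyntheticCohort:
    """Generate a cohort whose threshold-crossing users carry mention events.

    Users whose latent state first reaches ``mention_threshold`` on or
    after ``mention_min_day`` (the burn-in guaranteeing scorable
    history) receive one mention event.  With probability
    ``response_prob`` the event draws one-plus-Poisson responses at
    times uniform in (0, 72] hours, sharing a planted per-event
    favorability flag that selects the response vocabulary.  Responded
    users' latent state gains ``response_drift`` (plus
    ``favorable_drift`` when the responses are favorable) per day for
    ``mention_horizon`` days after the mention.
    """
    return _generate(config, with_mentions=True)


def simulate_interaction_rows(
    n_rows: int,
    interaction_effect: float,
    seed: int,
    beta_score: float = 0.2,
    beta_posts: float = 0.02,
    intercept: float = 0.5,
    noise_sd: float = 0.5,
) -> pd.DataFrame:
    """Regression rows with a planted score-by-volume interaction.

    Draws (mean_score, mean_posts) predictors directly and forms a
    continuous quantitative SI outcome

        si = intercept + beta_score * score + beta_posts * posts
             + interaction_effect * score * posts + N(0, noise_sd)

    This is the calibration harness for the interaction model:
    estimator bias and type-I error can be checked against the planted
    coefficient without the ordinal-thresholding attenuation of the
    full cohort generator.
    """
    rng = np.random.default_rng(seed)
    score = rng.uniform(0.2, 0.8, n_rows)
    posts = rng.poisson(3.0, n_rows) + 1.0
    si = (
        intercept
        + beta_score * score
        + beta_posts * posts
        + interaction_effect * score * posts
        + rng.normal(0.0, noise_sd, n_rows)
    )
    return pd.DataFrame({"si": si, "mean_score": score, "mean_posts": posts})
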