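"""Personalized scoring of responses to suicidal mentions.

After a user posts a *suicidal mention*, responses arriving within a
time window (default 72 h) may shape the poster's subsequent risk
trajectory.  To judge how personally favorable a response is, a
per-user model is built from the poster's own history: all historical
posts are risk-scored, the extreme low/high percentiles (default the
bottom and top 1%) are labeled 0/1, and a linear support-vector
regressor on bag-of-words counts is trained on those extremes.  Lower
output means the text resembles the user's most favorable (lowest-risk)
language, so low response scores denote personally *positive*
(favorable) messages.

Events are split into groups (responded vs not; positively vs
negatively scored responses) and each group's 21-day post-mention mean
daily risk curve is summarized by its Spearman correlation with time,
plus a two-sample comparison of the final window.
"""

from __future__ import annotations

import datetime as _dt
import math
from dataclasses import dataclass, field, replace
from typing import Callable, Literal, Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd
import scipy.stats as sps
from sklearn.feature_extraction.text import CountVectorizer
from sklearn.svm import LinearSVR

from .errors import (
    ClassError,
    ConfigurationError,
    DegenerateExtremesError,
    InputError,
    InsufficientHistoryError,
    PairingError,
    TokenizationError,
)
from .scoring import DailyScoreSeries, Post, RiskScorer, tokenize
from .stats import SpearmanResult, spearman

__all__ = [
    "Response",
    "MentionEvent",
    "PositivityModel",
    "ResponseScore",
    "filter_responses",
    "select_extremes",
    "train_positivity_model",
    "score_and_split",
    "post_mention_trajectory",
    "last_window_comparison",
    "GroupComparison",
]


@dataclass(frozen=True)
class Response:
    """One response to a suicidal mention."""

    ts: _dt.datetime
    responder_id: str
    text: str
    is_retweet: bool = False


@dataclass(frozen=True)
class MentionEvent:
    """A suicidal mention with its responses and the poster's prior history.

    Repeat mentions by one user are separate events (``event_id``
    disambiguates).  ``history`` holds the poster's posts strictly
    before ``mention_ts`` and feeds the personalized model.
    """

    user_id: str
    mention_ts: _dt.datetime
    responses: tuple[Response, ...] = ()
    history: tuple[Post, ...] = ()
    event_id: str = ""

    @property
    def key(self) -> str:
        return self.event_id or f"{self.user_id}@{self.mention_ts.isoformat()}"

    @property
    def mention_day(self) -> _dt.date:
        ts = self.mention_ts
        if ts.tzinfo is not None:
            ts = ts.astimezone(_dt.timezone.utc)
        return ts.date()


def filter_responses(event: MentionEvent, window_hours: float = 72.0) -> MentionEvent:
    """Keep responses within ``(0, window_hours]`` of the mention.

    The boundary is inclusive: a response at exactly ``window_hours``
    stays.  Retweets and the mentioning user's own replies are removed.
    """
    if window_hours <= 0:
        raise ConfigurationError("window_hours must be positive")
    kept = []
    for r in event.responses:
        if r.is_retweet or r.responder_id == event.user_id:
            continue
        dt_h = (r.ts - event.mention_ts).total_seconds() / 3600.0
        if 0 < dt_h <= window_hours:
            kept.append(r)
    return replace(event, responses=tuple(kept))


def select_extremes(
    history: Sequence[Post],
    scorer: RiskScorer,
    pct: float = 1.0,
    min_history: int = 200,
) -> tuple[list[Post], list[Post], tuple[float, float]]:
    """Pick the bottom/top ``pct`` percent of history by risk score.

    Returns ``(low_set, high_set, (low_cut, high_cut))`` where the low
    set holds the user's most favorable (lowest-scoring) posts and the
    high set the least favorable.  Each set contains
    ``max(ceil(pct/100 * n), 2)`` posts selected by rank — the floor of
    two keeps short histories trainable — and the sets never overlap
    (shrunk symmetrically if they would).  Identical scores throughout
    make the extremes indistinguishable and raise
    :class:`DegenerateExtremesError`.
    """
    if not 0 < pct < 50 and pct != 50:
        raise ConfigurationError("pct must be in (0, 50]")
    n = len(history)
    if n < min_history:
        raise InsufficientHistoryError(f"need >= {min_history} historical posts, got {n}")
    scores = np.array([scorer.score(p.text) for p in history])
    if np.ptp(scores) == 0:
        raise DegenerateExtremesError("all history scores identical; extremes undefined")
    k = max(math.ceil(pct / 100.0 * n), 2)
    k = min(k, n // 2)  # keep the sets disjoint
    order = np.argsort(scores, kind="stable")
    low_idx = order[:k]
    high_idx = order[n - k:]
    low = [history[i] for i in low_idx]
    high = [history[i] for i in high_idx]
    return low, high, (float(scores[low_idx].max()), float(scores[high_idx].min()))


@dataclass
class PositivityModel:
    """Per-user bag-of-words SVR over the user's extreme-scoring posts.

    Trained with low-extreme posts labeled 0 and high-extreme posts
    labeled 1, so lower outputs mean more personally positive
    (favorable) text.
    """

    user_id: str
    vocabulary: dict[str, int]
    weights: np.ndarray = field(repr=False)
    bias: float = 0.0
    pct_low_cut: float = float("nan")
    pct_high_cut: float = float("nan")

    def score(self, text: str) -> float:
        vec = np.zeros(len(self.vocabulary))
        for tok in tokenize(text):
            j = self.vocabulary.get(tok)
            if j is not None:
                vec[j] += 1
        return float(vec @ self.weights + self.bias)


def train_positivity_model(
    low_set: Sequence[Post],
    high_set: Sequence[Post],
    seed: int = 0,
    tokenizer: Callable[[str], list[str]] = tokenize,
    C: float = 1.0,
    cutpoints: tuple[float, float] = (float("nan"), float("nan")),
) -> PositivityModel:
    """Fit the personalized positivity SVR on labeled extreme posts."""
    if len(low_set) < 2 or len(high_set) < 2:
        raise InputError("each extreme set needs >= 2 posts")
    texts = [p.text for p in low_set] + [p.text for p in high_set]
    y = np.array([0.0] * len(low_set) + [1.0] * len(high_set))
    vec = CountVectorizer(analyzer=tokenizer)
    try:
        X = vec.fit_transform(texts)
    except ValueError as exc:
        raise TokenizationError(f"empty vocabulary after tokenization: {exc}") from exc
    if X.shape[1] == 0:
        raise TokenizationError("empty vocabulary after tokenization")
    svr = LinearSVR(C=C, epsilon=0.0, random_state=seed, max_iter=20_000)
    svr.fit(X, y)
    uid = low_set[0].user_id if low_set else ""
    return PositivityModel(
        user_id=uid,
        vocabulary={t: int(i) for t, i in vec.vocabulary_.items()},
        weights=np.asarray(svr.coef_, dtype=float).ravel(),
        bias=float(svr.intercept_[0]) if np.ndim(svr.intercept_) else float(svr.intercept_),
        pct_low_cut=cutpoints[0],
        pct_high_cut=cutpoints[1],
    )


class ResponseScore(NamedTuple):
    event_key: str
    user_id: str
    responder_id: str
    score: float
    group: str


def score_and_split(
    events: Sequence[MentionEvent],
    models: Mapping[str, PositivityModel],
    threshold: float | Literal["corpus_mean"] = "corpus_mean",
) -> tuple[list[ResponseScore], dict[str, str], float]:
    """Score responses with each mentioner's model and split events.

    Event-level positivity is the mean of its response scores.  The
    default threshold is the corpus mean of event-level scores (the
    published 0.243 is specific to its own data).  Events at or below
    the threshold form the ``positive`` (favorably responded) group —
    ties go positive by convention — the rest the ``negative`` group.
    """
    if not events:
        raise InputError("no events to score")
    event_scores: dict[str, float] = {}
    per_response: list[tuple[MentionEvent, Response, float]] = []
    for ev in events:
        model = models.get(ev.user_id)
        if model is None:
            raise PairingError(f"no trained model for user {ev.user_id!r}")
        if not ev.responses:
            raise InputError(f"event {ev.key} has no filtered responses")
        scores = [model.score(r.text) for r in ev.responses]
        event_scores[ev.key] = float(np.mean(scores))
        per_response.extend((ev, r, s) for r, s in zip(ev.responses, scores))
    thr = float(np.mean(list(event_scores.values()))) if threshold == "corpus_mean" else float(threshold)
    groups = {k: ("positive" if s <= thr else "negative") for k, s in event_scores.items()}
    scored = [
        ResponseScore(ev.key, ev.user_id, r.responder_id, s, groups[ev.key])
        for ev, r, s in per_response
    ]
    return scored, groups, thr


def post_mention_trajectory(
    grouped_events: Mapping[str, Sequence[MentionEvent]],
    series_by_user: Mapping[str, DailyScoreSeries],
    horizon_days: int = 21,
    mode: Literal["group_mean", "pooled"] = "group_mean",
) -> dict[str, tuple[pd.DataFrame, SpearmanResult]]:
    """Group-level post-mention risk trajectories over ``horizon_days``.

    Day 0 is the UTC calendar day of the mention.  For each group the
    per-day mean of members' mean daily scores forms a curve; its
    Spearman correlation with the day index (two-tailed) summarizes the
    temporal direction.  ``mode="pooled"`` instead correlates the
    pooled (day, member-value) points.  Days with no contributing
    member are missing from the curve and excluded from the
    correlation.
    """
    if horizon_days < 3:
        raise ConfigurationError("horizon_days must be >= 3")
    out: dict[str, tuple[pd.DataFrame, SpearmanResult]] = {}
    for group, events in grouped_events.items():
        rows = []
        for ev in events:
            series = series_by_user.get(ev.user_id)
            if series is None:
                continue
            d0 = ev.mention_day
            for d in range(horizon_days):
                v = series.get(d0 + _dt.timedelta(days=d))
                if v is not None:
                    rows.append((d, v))
        pooled = pd.DataFrame(rows, columns=["day", "score"])
        curve = pooled.groupby("day")["score"].agg(mean_score="mean", n="size").reset_index()
        if mode == "group_mean":
            res = spearman(curve["day"], curve["mean_score"]) if len(curve) >= 3 else SpearmanResult(
                float("nan"), float("nan"), len(curve)
            )
        else:
            res = spearman(pooled["day"], pooled["score"]) if len(pooled) >= 3 else SpearmanResult(
                float("nan"), float("nan"), len(pooled)
            )
        out[group] = (curve, res)
    return out


class GroupComparison(NamedTuple):
    mean_a: float
    mean_b: float
    n_a: int
    n_b: int
    statistic: float
    p: float
    test: str


def last_window_comparison(
    grouped_events: Mapping[str, Sequence[MentionEvent]],
    series_by_user: Mapping[str, DailyScoreSeries],
    horizon_days: int = 21,
    last_days: int = 7,
    test: Literal["auto", "t", "mannwhitney"] = "auto",
) -> GroupComparison:
    """Compare per-member means over the final ``last_days`` of the horizon.

    Exactly two groups are required (order follows the mapping).  Each
    member contributes its mean daily score over days
    ``[horizon - last_days, horizon)`` after its mention.  The default
    routes through the normality gate: Student's two-tailed t test when
    both samples pass, Mann-Whitney U otherwise (always nonparametric
    when either group is too small to gate).
    """
    from .association import normality_gate  # local import avoids a cycle

    if last_days < 1 or last_days > horizon_days:
        raise ConfigurationError("last_days must be in [1, horizon_days]")
    names = list(grouped_events)
    if len(names) != 2:
        raise InputError(f"need exactly 2 groups, got {names}")
    samples: list[np.ndarray] = []
    for g in names:
        vals = []
        for ev in grouped_events[g]:
            series = series_by_user.get(ev.user_id)
            if series is None:
                continue
            d0 = ev.mention_day
            days = [
                series.get(d0 + _dt.timedelta(days=d))
                for d in range(horizon_days - last_days, horizon_days)
            ]
            days = [v for v in days if v is not None]
            if days:
                vals.append(float(np.mean(days)))
        samples.append(np.asarray(vals))
    a, b = samples
    if len(a) == 0 or len(b) == 0:
        raise ClassError("both groups need at least one member with scored days")
    chosen = test
    if test == "auto":
        if len(a) >= 8 and len(b) >= 8:
            gates = {normality_gate(a), normality_gate(b)}
            chosen = "t" if gates == {"parametric"} else "mannwhitney"
        else:
            chosen = "mannwhitney"
    if chosen == "t":
        stat, p = sps.ttest_ind(a, b)
    else:
        stat, p = sps.mannwhitneyu(a, b, alternative="two-sided")
    return GroupComparison(
        float(np.mean(a)), float(np.mean(b)), len(a), len(b), float(stat), float(p), chosen
    )
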