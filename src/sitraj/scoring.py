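"""Post-level risk scoring and daily aggregation.

A *risk scorer* maps a single text to a score in [0, 1], higher meaning
higher indicated suicide risk.  Any object satisfying the
:class:`RiskScorer` protocol can be plugged into the pipeline; two
implementations ship with the package:

* :class:`LexiconRiskScorer` — a transparent hit-rate scorer over a
  risk/protective word list pair, used throughout the synthetic studies.
* :func:`reference_scorer_fit` — a construct-lexicon + random-forest
  scorer in the spirit of published text-to-risk models: each post is
  reduced to normalized per-construct lexicon hit rates (depression,
  hopelessness, loneliness, ...) and a random forest trained on
  case/control posts converts the construct vector into a case
  probability.

Post-level scores are aggregated to **mean daily scores** per UTC
calendar day, the fundamental unit of every downstream analysis, and
windowed means anchored to reference (survey) days are computed with a
minimum-posts-per-day filter.
"""

from __future__ import annotations

import datetime as _dt
import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, NamedTuple, Protocol, Sequence, runtime_checkable

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier

from .errors import ConfigurationError, FittingError, InputError

__all__ = [
    "Post",
    "DailyScoreSeries",
    "RiskScorer",
    "LexiconRiskScorer",
    "ReferenceRiskScorer",
    "reference_scorer_fit",
    "aggregate_daily",
    "windowed_mean",
    "WindowStats",
    "tokenize",
]

_URL_RE = re.compile(r"(?:https?://\S+|www\.\S+)")
_HANDLE_RE = re.compile(r"@\w+")
_TOKEN_RE = re.compile(r"[a-z0-9]+(?:'[a-z]+)*")


def tokenize(text: str) -> list[str]:
    """Lowercase, strip URLs and @-handles, keep apostrophized negations.

    Contractions such as ``don't`` stay single tokens (curly apostrophes
    are normalized to straight ones first), since they are meaningful
    units in response-language analyses.
    """
    text = text.replace("’", "'").lower()
    text = _URL_RE.sub(" ", text)
    text = _HANDLE_RE.sub(" ", text)
    return _TOKEN_RE.findall(text)


@dataclass(frozen=True)
class Post:
    """One social-media post: author, UTC timestamp, text."""

    user_id: str
    timestamp: _dt.datetime
    text: str

    def __post_init__(self) -> None:
        if not self.text.strip():
            raise InputError("Post.text is empty after whitespace stripping")

    @property
    def day(self) -> _dt.date:
        """UTC calendar day of the post."""
        ts = self.timestamp
        if ts.tzinfo is not None:
            ts = ts.astimezone(_dt.timezone.utc)
        return ts.date()


@runtime_checkable
class RiskScorer(Protocol):
    """Contract for post-level risk scorers: deterministic, [0, 1], higher = riskier."""

    name: str
    version: str

    def score(self, text: str) -> float:  # pragma: no cover - protocol
        ...


@dataclass
class LexiconRiskScorer:
    """Hit-rate scorer: fraction of signal words that come from the risk list.

    ``score = (risk hits + 0.5) / (risk hits + protective hits + 1)``, a
    Laplace-smoothed ratio that returns 0.5 for texts with no signal
    words.  Deterministic and stateless; mainly used to score synthetic
    corpora whose generative lexicons are known.
    """

    risk_words: frozenset[str]
    protective_words: frozenset[str]
    name: str = "lexicon"
    version: str = "1"

    def __init__(self, risk_words: Iterable[str], protective_words: Iterable[str]):
        self.risk_words = frozenset(w.lower() for w in risk_words)
        self.protective_words = frozenset(w.lower() for w in protective_words)
        if not self.risk_words or not self.protective_words:
            raise ConfigurationError("risk_words and protective_words must be nonempty")
        self.name = "lexicon"
        self.version = "1"

    def score(self, text: str) -> float:
        toks = tokenize(text)
        r = sum(t in self.risk_words for t in toks)
        p = sum(t in self.protective_words for t in toks)
        return (r + 0.5) / (r + p + 1.0)


def _construct_vector(text: str, lexicons: Mapping[str, frozenset[str]]) -> np.ndarray:
    toks = tokenize(text)
    n = max(len(toks), 1)
    return np.array([sum(t in lex for t in toks) / n for lex in lexicons.values()])


@dataclass
class ReferenceRiskScorer:
    """Construct-lexicon + random-forest scorer.

    Each text is converted to a vector of normalized hit rates over named
    psychological-construct lexicons; a random forest trained on
    case/control posts maps that vector to a case probability in [0, 1].
    Fitted state is frozen at construction, so scoring is deterministic.
    """

    lexicons: dict[str, frozenset[str]]
    forest: RandomForestClassifier
    case_index: int
    name: str = "reference-rf"
    version: str = "1"

    def score(self, text: str) -> float:
        x = _construct_vector(text, self.lexicons).reshape(1, -1)
        return float(self.forest.predict_proba(x)[0, self.case_index])

    def score_many(self, texts: Sequence[str]) -> np.ndarray:
        X = np.vstack([_construct_vector(t, self.lexicons) for t in texts])
        return self.forest.predict_proba(X)[:, self.case_index]


def reference_scorer_fit(
    labeled_posts: Sequence[tuple[str, str]],
    lexicons: Mapping[str, Iterable[str]],
    seed: int,
    n_estimators: int = 200,
) -> ReferenceRiskScorer:
    """Fit the construct-lexicon random-forest scorer.

    Parameters
    ----------
    labeled_posts
        ``(text, label)`` pairs with labels ``"case"`` / ``"control"``.
    lexicons
        Mapping construct name -> word list; per-post features are the
        normalized hit rates of each lexicon.
    seed
        Random-forest seed; fitting is deterministic given it.
    """
    if not lexicons or any(not list(words) for words in lexicons.values()):
        raise ConfigurationError("every construct lexicon must be nonempty")
    labels = [lab for _, lab in labeled_posts]
    classes = sorted(set(labels))
    if len(classes) < 2:
        raise FittingError("labeled_posts must contain both 'case' and 'control'")
    lexsets = {k: frozenset(w.lower() for w in v) for k, v in lexicons.items()}
    X = np.vstack([_construct_vector(t, lexsets) for t, _ in labeled_posts])
    y = np.array([lab == "case" for lab in labels], dtype=int)
    forest = RandomForestClassifier(n_estimators=n_estimators, random_state=seed)
    forest.fit(X, y)
    case_index = int(np.where(forest.classes_ == 1)[0][0])
    return ReferenceRiskScorer(lexicons=lexsets, forest=forest, case_index=case_index)


@dataclass
class DailyScoreSeries:
    """Per-user mean daily risk score and post count.

    ``frame`` is indexed by calendar date (``datetime.date``), strictly
    increasing, with columns ``mean_score`` (in [0, 1]) and
    ``post_count`` (>= 1).  Days with no posts are absent, never
    imputed to zero; explicit gap filling lives in the forecasting
    module and flags its output.
    """

    user_id: str
    frame: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        f = self.frame
        required = {"mean_score", "post_count"}
        if not required.issubset(f.columns):
            raise InputError(f"DailyScoreSeries frame needs columns {sorted(required)}")
        days = np.asarray(f.index)
        if len(days) > 1 and not all(days[i] < days[i + 1] for i in range(len(days) - 1)):
            raise InputError("DailyScoreSeries days must be strictly increasing")
        observed = f
        if "imputed" in f.columns:
            observed = f.loc[~f["imputed"].astype(bool)]
        if (observed["post_count"] < 1).any():
            raise InputError("mean_score is defined only on days with post_count >= 1")
        scores = f["mean_score"].to_numpy(dtype=float)
        if np.nanmin(scores, initial=0.0) < -1e-12 or np.nanmax(scores, initial=0.0) > 1 + 1e-12:
            raise InputError("mean_score must lie in [0, 1]")
        # flat caches for windowing hot paths
        self._ordinals = np.array([d.toordinal() for d in f.index], dtype=np.int64)
        self._scores = scores
        self._counts = f["post_count"].to_numpy(dtype=float)
        self._by_day = dict(zip(f.index, scores))

    @classmethod
    def from_days(
        cls,
        user_id: str,
        days: Sequence[_dt.date],
        mean_scores: Sequence[float],
        post_counts: Sequence[int],
    ) -> "DailyScoreSeries":
        frame = pd.DataFrame(
            {"mean_score": list(mean_scores), "post_count": list(post_counts)},
            index=pd.Index(list(days), name="date"),
        )
        return cls(user_id=user_id, frame=frame.sort_index())

    @property
    def days(self) -> list[_dt.date]:
        return list(self.frame.index)

    @property
    def span_days(self) -> int:
        """Calendar span, first to last scored day inclusive (0 if empty)."""
        if self.frame.empty:
            return 0
        return (self.frame.index[-1] - self.frame.index[0]).days + 1

    def __len__(self) -> int:
        return len(self.frame)

    def get(self, day: _dt.date) -> float | None:
        """Mean score on ``day`` or None if unscored."""
        v = self._by_day.get(day)
        return None if v is None else float(v)


def aggregate_daily(posts: Sequence[Post], scorer: RiskScorer) -> DailyScoreSeries:
    """Score each post and average within UTC calendar days.

    All posts must share one ``user_id``.  Days without posts are simply
    absent from the series.  An empty post list yields an empty series
    with ``user_id`` ``""``.
    """
    if not posts:
        return DailyScoreSeries(
            user_id="",
            frame=pd.DataFrame(columns=["mean_score", "post_count"], index=pd.Index([], name="date")),
        )
    uids = {p.user_id for p in posts}
    if len(uids) != 1:
        raise InputError(f"aggregate_daily requires a single user_id, got {sorted(uids)}")
    rows = [(p.day, scorer.score(p.text)) for p in posts]
    df = pd.DataFrame(rows, columns=["date", "score"])
    agg = df.groupby("date")["score"].agg(mean_score="mean", post_count="size")
    agg.index.name = "date"
    return DailyScoreSeries(user_id=uids.pop(), frame=agg.sort_index())


class WindowStats(NamedTuple):
    """Result of a windowed mean; NaN fields signal a missing value."""

    mean_score: float
    mean_posts: float
    n_days_used: int

    @property
    def missing(self) -> bool:
        return self.n_days_used == 0


def windowed_mean(
    series: DailyScoreSeries,
    anchor_day: _dt.date,
    window_days: int,
    min_posts_per_day: int = 0,
    include_anchor: bool = False,
) -> WindowStats:
    """Average daily scores over the ``window_days`` days before ``anchor_day``.

    The window covers ``[anchor - window_days, anchor - 1]``; with
    ``include_anchor`` it covers ``[anchor - window_days + 1, anchor]``,
    so a window of length D always spans exactly D calendar days.  Only
    days with ``post_count >= max(1, min_posts_per_day)`` qualify.  If no
    day qualifies the result carries NaN means and ``n_days_used == 0``
    — a missing value to be propagated, never silently zero.
    """
    if window_days < 1:
        raise ConfigurationError("window_days must be >= 1")
    if include_anchor:
        lo = anchor_day - _dt.timedelta(days=window_days - 1)
        hi = anchor_day
    else:
        lo = anchor_day - _dt.timedelta(days=window_days)
        hi = anchor_day - _dt.timedelta(days=1)
    if series.frame.empty:
        return WindowStats(float("nan"), float("nan"), 0)
    ords = series._ordinals
    i0 = int(np.searchsorted(ords, lo.toordinal(), side="left"))
    i1 = int(np.searchsorted(ords, hi.toordinal(), side="right"))
    counts = series._counts[i0:i1]
    mask = counts >= max(1, min_posts_per_day)
    n = int(mask.sum())
    if n == 0:
        return WindowStats(float("nan"), float("nan"), 0)
    scores = series._scores[i0:i1]
    return WindowStats(float(scores[mask].mean()), float(counts[mask].mean()), n)
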