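"""Personalized next-day risk-score forecasting.

Per user, an ensemble of linear-kernel support-vector regressors is
trained on lagged windows of the mean daily score series, the target
being the next day's mean.  Window lengths start at 14 days and step by
7 until they reach or exceed half the user's available day span
(first qualifying window included), so a user with a 100-day history
gets windows 14, 21, ..., 56.  A forecast is the equal-weight average
of the predictions of every window whose lag days are fully covered by
data — the operative "stacked" combination here is plain averaging,
not a learned meta-model.  Windows with gaps in their lag vector are
excluded; if none apply, the forecast is unavailable rather than
guessed.

Hyperparameters are fixed (C = 1.0, epsilon = 0, squared
epsilon-insensitive loss, iteration cap) rather than tuned per user:
with many small models per individual, a simple held-out comparison
against the realized next-day values is the validation strategy, not
internal cross-validation.  Epsilon zero keeps a constant series
reproduced exactly instead of anywhere inside an insensitivity tube;
the L2-loss SVR variant, fit in the primal on mean-centered features,
is used because the dual L1 solver both regularizes the intercept
toward zero (a real bias when scores center near 0.5) and converges
poorly on the longest windows, where the number of lag features
approaches the number of training positions.

Gap filling by recursive one-day-ahead forecasting is provided as an
explicitly approximate convenience (`fill_gaps`); filled days are
flagged ``imputed`` and carry ``post_count`` 0.
"""

from __future__ import annotations

import datetime as _dt
import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.svm import LinearSVR

from .errors import (
    ConfigurationError,
    FittingError,
    InsufficientHistoryError,
    PredictionUnavailableError,
)
from .scoring import DailyScoreSeries

__all__ = [
    "ForecastEnsemble",
    "build_window_set",
    "train_ensemble",
    "predict_next",
    "fill_gaps",
    "last_value_baseline",
]

MIN_WINDOW = 14
WINDOW_STEP = 7


def build_window_set(available_days: int) -> list[int]:
    """Lag-window lengths for a user with ``available_days`` of history.

    ``max_range = floor(available_days / 2)``; windows are 14, 21, 28,
    ... and the first window reaching or exceeding ``max_range`` is the
    last one included.  Fewer than 28 available days leave
    ``max_range`` below the 14-day minimum and raise
    :class:`InsufficientHistoryError`.
    """
    if available_days < 2 * MIN_WINDOW:
        raise InsufficientHistoryError(
            f"need >= {2 * MIN_WINDOW} available days, got {available_days}"
        )
    max_range = available_days // 2
    windows = [MIN_WINDOW]
    while windows[-1] < max_range:
        windows.append(windows[-1] + WINDOW_STEP)
    return windows


@dataclass
class ForecastEnsemble:
    """Per-user set of window-trained linear SVRs (weights + bias)."""

    user_id: str
    windows: list[int]
    coefs: dict[int, np.ndarray] = field(repr=False)
    intercepts: dict[int, float] = field(repr=False)
    n_examples: dict[int, int] = field(default_factory=dict)
    training_span_days: int = 0
    seed: int = 0

    def predict_window(self, w: int, lags: np.ndarray) -> float:
        """Prediction of window ``w`` from its lag vector (oldest first)."""
        return float(lags @ self.coefs[w] + self.intercepts[w])

    def to_json(self) -> str:
        return json.dumps(
            {
                "user_id": self.user_id,
                "windows": self.windows,
                "models": {
                    str(w): {
                        "weights": self.coefs[w].tolist(),
                        "bias": self.intercepts[w],
                        "n_examples": self.n_examples.get(w, 0),
                    }
                    for w in self.windows
                },
                "training_span_days": self.training_span_days,
                "seed": self.seed,
            }
        )

    @classmethod
    def from_json(cls, payload: str) -> "ForecastEnsemble":
        d = json.loads(payload)
        windows = [int(w) for w in d["windows"]]
        return cls(
            user_id=d["user_id"],
            windows=windows,
            coefs={int(w): np.asarray(m["weights"], dtype=float) for w, m in d["models"].items()},
            intercepts={int(w): float(m["bias"]) for w, m in d["models"].items()},
            n_examples={int(w): int(m["n_examples"]) for w, m in d["models"].items()},
            training_span_days=int(d["training_span_days"]),
            seed=int(d["seed"]),
        )


def _series_arrays(series: DailyScoreSeries) -> tuple[_dt.date, np.ndarray, np.ndarray]:
    """(first day, presence mask, value array) over the series' calendar span."""
    f = series.frame
    first = f.index[0]
    span = series.span_days
    present = np.zeros(span, dtype=bool)
    values = np.full(span, np.nan)
    for d, row in zip(f.index, f["mean_score"].to_numpy(float)):
        i = (d - first).days
        present[i] = True
        values[i] = row
    return first, present, values


def train_ensemble(
    series: DailyScoreSeries,
    seed: int = 0,
    windows: Sequence[int] | None = None,
    C: float = 1.0,
    epsilon: float = 0.0,
    max_iter: int = 20_000,
) -> ForecastEnsemble:
    """Train the per-user lag-window SVR ensemble.

    For each window length w, training examples are every position
    (stride 1) where w consecutive daily means and the following day
    are all observed; the feature vector is those w means oldest-first
    and the target is the next day's mean.  Windows with no complete
    example are dropped with a warning; an ensemble with no surviving
    window raises :class:`FittingError`.  Deterministic given ``seed``.
    """
    if windows is None:
        windows = build_window_set(series.span_days)
    first, present, values = _series_arrays(series)
    span = len(present)
    coefs: dict[int, np.ndarray] = {}
    intercepts: dict[int, float] = {}
    n_examples: dict[int, int] = {}
    kept: list[int] = []
    for w in windows:
        X_rows = []
        y_rows = []
        for t in range(w, span):
            if present[t] and present[t - w:t].all():
                X_rows.append(values[t - w:t])
                y_rows.append(values[t])
        if not X_rows:
            import warnings

            warnings.warn(f"window {w}: no complete training example; dropped", stacklevel=2)
            continue
        X = np.vstack(X_rows)
        y = np.asarray(y_rows)
        # center so the (liblinear-regularized) intercept sits at zero
        mu = X.mean(axis=0)
        ym = float(y.mean())
        svr = LinearSVR(
            C=C,
            epsilon=epsilon,
            loss="squared_epsilon_insensitive",
            dual=False,
            random_state=seed,
            max_iter=max_iter,
        )
        svr.fit(X - mu, y - ym)
        coef = np.asarray(svr.coef_, dtype=float).ravel()
        b = float(np.atleast_1d(svr.intercept_)[0])
        coefs[w] = coef
        # fold the centering back into an affine form over raw lags
        intercepts[w] = b + ym - float(mu @ coef)
        n_examples[w] = len(X_rows)
        kept.append(w)
    if not kept:
        raise FittingError("every window was dropped; nothing trainable")
    return ForecastEnsemble(
        user_id=series.user_id,
        windows=kept,
        coefs=coefs,
        intercepts=intercepts,
        n_examples=n_examples,
        training_span_days=series.span_days,
        seed=seed,
    )


def predict_next(
    ensemble: ForecastEnsemble,
    series: DailyScoreSeries,
    target_day: _dt.date,
) -> float:
    """Equal-weight ensemble forecast of ``target_day``'s mean score.

    Each window contributes only if every one of its lag days
    (the w days strictly before ``target_day``) is observed; windows
    with gaps are excluded.  The average of contributing predictions is
    clipped to [0, 1].  No window applicable raises
    :class:`PredictionUnavailableError`.  Data on or after
    ``target_day`` are never read.
    """
    f = series.frame
    lookup = dict(zip(f.index, f["mean_score"].to_numpy(float)))
    preds = []
    for w in ensemble.windows:
        lag_days = [target_day - _dt.timedelta(days=w - j) for j in range(w)]
        vals = [lookup.get(d) for d in lag_days]
        if any(v is None for v in vals):
            continue
        preds.append(ensemble.predict_window(w, np.asarray(vals, dtype=float)))
    if not preds:
        raise PredictionUnavailableError(
            f"no window has complete lag coverage before {target_day}"
        )
    return float(np.clip(np.mean(preds), 0.0, 1.0))


def last_value_baseline(series: DailyScoreSeries, target_day: _dt.date) -> float:
    """Naive baseline: most recent observed mean strictly before the target."""
    f = series.frame
    prior = [d for d in f.index if d < target_day]
    if not prior:
        raise PredictionUnavailableError(f"no observation before {target_day}")
    return float(f.loc[prior[-1], "mean_score"])


def fill_gaps(series: DailyScoreSeries, ensemble: ForecastEnsemble) -> DailyScoreSeries:
    """Fill interior missing days by recursive one-day-ahead forecasting.

    Missing days between the first and last observation are filled in
    chronological order using observed plus previously filled values;
    filled rows are flagged ``imputed`` with ``post_count`` 0.  Days
    whose lag windows cannot be completed (e.g. gaps too early in the
    history) stay unfilled.  A series with no observations is returned
    unchanged with a warning.
    """
    if ensemble.user_id != series.user_id:
        raise ConfigurationError("ensemble and series belong to different users")
    f = series.frame
    if f.empty:
        import warnings

        warnings.warn("series has no observed days; nothing to fill", stacklevel=2)
        return series
    out = f.copy()
    if "imputed" not in out.columns:
        out["imputed"] = False
    first, last = f.index[0], f.index[-1]
    day = first
    while day <= last:
        if day not in out.index:
            work = DailyScoreSeries(user_id=series.user_id, frame=out.sort_index())
            try:
                v = predict_next(ensemble, work, day)
            except PredictionUnavailableError:
                v = None
            if v is not None:
                out.loc[day, ["mean_score", "post_count", "imputed"]] = [v, 0, True]
                out = out.sort_index()
        day += _dt.timedelta(days=1)
    return DailyScoreSeries(user_id=series.user_id, frame=out.sort_index())
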