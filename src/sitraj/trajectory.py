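"""Within-person coupling of risk-score change and SI change.

For each user's successive pair of survey entries, the change in the
ordinal SI item per day (``si_slope``) is paired with the change in
mean daily risk score per day (``score_slope``), either as a
least-squares slope over every scored day between the entries
(``all_days_between``) or as the difference quotient of the two entry
days (``entry_days_only``).  The pairs feed

* a linear interaction model
  ``si_slope ~ score_slope + delta_days + score_slope:delta_days``
  (time between surveys modulates how well score change tracks SI
  change), with robust routing via the normality gate, and
* a threshold scan correlating the two slopes (Spearman) over pairs
  whose inter-survey gap is at most T, for T from 10 to 100 days —
  coupling concentrates at short gaps because longer intervals hide
  unmeasured excursions.

An event-aligned group comparison (e.g. around a population-level
stressor) is also provided.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.stats as sps

from .association import (
    InteractionFit,
    SurveyObservation,
    fit_interaction_model,
    normality_gate,
)
from .errors import (
    ClassError,
    ConfigurationError,
    InputError,
    SampleSizeError,
    WindowError,
)
from .scoring import DailyScoreSeries
from .stats import SpearmanResult, spearman

__all__ = [
    "SlopePair",
    "build_slope_pairs",
    "slope_interaction_model",
    "gap_threshold_scan",
    "event_aligned_comparison",
]

SlopeMode = Literal["all_days_between", "entry_days_only"]


@dataclass(frozen=True)
class SlopePair:
    """Slopes between one successive pair of survey entries."""

    user_id: str
    t0: _dt.date
    t1: _dt.date
    delta_days: int
    si_slope: float
    score_slope: float
    score_slope_mode: SlopeMode

    def __post_init__(self) -> None:
        if self.delta_days < 1:
            raise InputError("delta_days must be >= 1")
        if not (np.isfinite(self.si_slope) and np.isfinite(self.score_slope)):
            raise InputError("slopes must be finite")


def _lsq_slope(days: np.ndarray, values: np.ndarray) -> float:
    """Least-squares slope via the normal equations (x centered)."""
    x = days - days.mean()
    return float((x @ values) / (x @ x))


def build_slope_pairs(
    series_by_user: Mapping[str, DailyScoreSeries],
    surveys: Sequence[SurveyObservation],
    mode: SlopeMode = "all_days_between",
) -> list[SlopePair]:
    """Pair successive survey entries with the matching score slope.

    ``si_slope`` is always ``(si1 - si0) / delta_days``.  In
    ``all_days_between`` mode ``score_slope`` is the least-squares slope
    of mean daily scores over every scored day in the closed interval
    ``[t0, t1]`` (pairs with fewer than 2 scored days are dropped); in
    ``entry_days_only`` it is the difference quotient of the two entry
    days' means (pairs missing either day are dropped).  Per-user survey
    dates must be strictly increasing.
    """
    if mode not in ("all_days_between", "entry_days_only"):
        raise ConfigurationError(f"unknown mode {mode!r}")
    by_user: dict[str, list[SurveyObservation]] = {}
    for obs in surveys:
        by_user.setdefault(obs.user_id, []).append(obs)
    pairs: list[SlopePair] = []
    for uid, obs_list in by_user.items():
        dates = [o.date for o in obs_list]
        if any(dates[i] >= dates[i + 1] for i in range(len(dates) - 1)):
            raise InputError(f"survey dates for {uid!r} must be strictly increasing")
        series = series_by_user.get(uid)
        if series is None or len(obs_list) < 2:
            continue
        for o0, o1 in zip(obs_list, obs_list[1:]):
            delta = (o1.date - o0.date).days
            si_slope = (o1.si - o0.si) / delta
            if mode == "entry_days_only":
                s0, s1 = series.get(o0.date), series.get(o1.date)
                if s0 is None or s1 is None:
                    continue
                score_slope = (s1 - s0) / delta
            else:
                f = series.frame
                in_interval = [o0.date <= d <= o1.date for d in f.index]
                sub = f.loc[in_interval]
                if len(sub) < 2:
                    continue
                days = np.array([(d - o0.date).days for d in sub.index], dtype=float)
                score_slope = _lsq_slope(days, sub["mean_score"].to_numpy(float))
            pairs.append(
                SlopePair(
                    user_id=uid,
                    t0=o0.date,
                    t1=o1.date,
                    delta_days=delta,
                    si_slope=si_slope,
                    score_slope=score_slope,
                    score_slope_mode=mode,
                )
            )
    return pairs


def pairs_frame(pairs: Sequence[SlopePair]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "user_id": [p.user_id for p in pairs],
            "t0": [p.t0 for p in pairs],
            "t1": [p.t1 for p in pairs],
            "delta_days": [p.delta_days for p in pairs],
            "si_slope": [p.si_slope for p in pairs],
            "score_slope": [p.score_slope for p in pairs],
            "mode": [p.score_slope_mode for p in pairs],
        }
    )


def slope_interaction_model(
    pairs: Sequence[SlopePair],
    method: Literal["auto", "ols", "robust"] = "auto",
    alpha: float = 0.05,
) -> InteractionFit:
    """Fit ``si_slope ~ score_slope * delta_days`` over slope pairs.

    With ``method="auto"`` the OLS residuals pass through the
    Anderson-Darling normality gate; rejection reroutes to Huber robust
    regression, mirroring the parametric/robust routing of the rest of
    the package.
    """
    if len(pairs) < 6:
        raise SampleSizeError(f"need >= 6 slope pairs, got {len(pairs)}")
    rows = pd.DataFrame(
        {
            "si": [p.si_slope for p in pairs],
            "mean_score": [p.score_slope for p in pairs],
            "mean_posts": [float(p.delta_days) for p in pairs],
        }
    )
    fit = fit_interaction_model(rows, method="ols")
    if method == "ols":
        return fit
    if method == "robust":
        return fit_interaction_model(rows, method="robust")
    # auto: gate the OLS residuals
    X = np.column_stack(
        [
            np.ones(len(rows)),
            rows["mean_score"],
            rows["mean_posts"],
            rows["mean_score"] * rows["mean_posts"],
        ]
    )
    beta, *_ = np.linalg.lstsq(X, rows["si"].to_numpy(float), rcond=None)
    resid = rows["si"].to_numpy(float) - X @ beta
    if len(resid) >= 8 and normality_gate(resid, alpha=alpha) == "nonparametric":
        return fit_interaction_model(rows, method="robust")
    return fit


def gap_threshold_scan(
    pairs: Sequence[SlopePair],
    thresholds: Sequence[int] = tuple(range(10, 101)),
    correlation: Literal["spearman"] = "spearman",
) -> pd.DataFrame:
    """Spearman coupling of the two slopes under a maximum-gap threshold.

    For each threshold T the correlation of ``si_slope`` with
    ``score_slope`` is computed over pairs with ``delta_days <= T``.
    Thresholds with fewer than 4 pairs, or zero variance in either
    slope, are marked missing with a reason.  No multiplicity
    correction.
    """
    if correlation != "spearman":
        raise ConfigurationError("only spearman correlation is supported")
    thresholds = list(thresholds)
    if any(t1 >= t2 for t1, t2 in zip(thresholds, thresholds[1:])):
        raise ConfigurationError("thresholds must be strictly increasing")
    deltas = np.array([p.delta_days for p in pairs])
    si = np.array([p.si_slope for p in pairs])
    sc = np.array([p.score_slope for p in pairs])
    rows = []
    for t in thresholds:
        mask = deltas <= t
        n = int(mask.sum())
        if n < 4:
            rows.append({"threshold": t, "rho": np.nan, "p": np.nan, "n": n,
                         "reason": "fewer than 4 pairs"})
            continue
        if np.ptp(si[mask]) == 0 or np.ptp(sc[mask]) == 0:
            rows.append({"threshold": t, "rho": np.nan, "p": np.nan, "n": n,
                         "reason": "zero variance"})
            continue
        res = spearman(sc[mask], si[mask])
        rows.append({"threshold": t, "rho": res.rho, "p": res.p, "n": n, "reason": ""})
    return pd.DataFrame(rows)


def event_aligned_comparison(
    series_by_user: Mapping[str, DailyScoreSeries],
    groups: Mapping[str, Literal["exposed", "control"]],
    event_date: _dt.date,
    pre_days: int,
    post_days: int,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-day two-sample comparison of group means around an event.

    Daily means are aligned so day 0 is ``event_date``; for each day in
    ``[-pre_days, post_days]`` the exposed and control samples are
    compared with Student's t or Mann-Whitney U, chosen by the
    normality gate (nonparametric whenever a sample is too small to
    gate).  Returns one row per day with group means, sample sizes, the
    statistic, p, and the test used; days with either group empty are
    skipped.
    """
    if pre_days < 0 or post_days < 0:
        raise ConfigurationError("pre_days and post_days must be nonnegative")
    names = set(groups.values())
    if "exposed" not in names or "control" not in names:
        raise ClassError("groups must contain both 'exposed' and 'control' users")
    rows = []
    for offset in range(-pre_days, post_days + 1):
        day = event_date + _dt.timedelta(days=offset)
        samples: dict[str, list[float]] = {"exposed": [], "control": []}
        for uid, g in groups.items():
            series = series_by_user.get(uid)
            if series is None:
                continue
            v = series.get(day)
            if v is not None:
                samples[g].append(v)
        a = np.asarray(samples["exposed"])
        b = np.asarray(samples["control"])
        if len(a) == 0 or len(b) == 0:
            continue
        if len(a) >= 8 and len(b) >= 8 and np.ptp(a) > 0 and np.ptp(b) > 0:
            gates = {normality_gate(a, alpha), normality_gate(b, alpha)}
            test = "t" if gates == {"parametric"} else "mannwhitney"
        else:
            test = "mannwhitney"
        if test == "t":
            stat, p = sps.ttest_ind(a, b)
        else:
            stat, p = sps.mannwhitneyu(a, b, alternative="two-sided")
        rows.append(
            {
                "day": offset,
                "mean_exposed": float(a.mean()),
                "mean_control": float(b.mean()),
                "n_exposed": len(a),
                "n_control": len(b),
                "statistic": float(stat),
                "p": float(p),
                "test": test,
            }
        )
    if not rows:
        raise WindowError("no day in the alignment window has data for both groups")
    return pd.DataFrame(rows)
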