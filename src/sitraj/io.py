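"""Readers and writers for the pipeline's plain-text formats.

All timestamps are serialized ISO-8601 UTC; dates are calendar days.
Formats:

* ``posts.jsonl`` — one post per line: user_id, timestamp, text
* ``surveys.csv`` — user_id, date, si, scale, stress, anxiety, depression
* ``mentions.jsonl`` — one mention event per line with its responses
* ``daily_scores.csv`` — user_id, date, mean_score, post_count
* ``truth.json`` — synthetic-cohort ground truth

Every writer/reader pair round-trips without loss.
"""

from __future__ import annotations

import datetime as _dt
import json
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .association import SurveyObservation
from .positivity import MentionEvent, Response
from .scoring import DailyScoreSeries, Post

__all__ = [
    "write_posts",
    "read_posts",
    "write_surveys",
    "read_surveys",
    "write_mentions",
    "read_mentions",
    "write_daily_scores",
    "read_daily_scores",
    "write_truth",
    "read_truth",
]

_COVARIATES = ("stress", "anxiety", "depression")


def _iso(ts: _dt.datetime) -> str:
    if ts.tzinfo is None:
        ts = ts.replace(tzinfo=_dt.timezone.utc)
    return ts.astimezone(_dt.timezone.utc).isoformat()


def _parse_ts(s: str) -> _dt.datetime:
    return _dt.datetime.fromisoformat(s).astimezone(_dt.timezone.utc)


def write_posts(path: str | Path, posts: Iterable[Post]) -> int:
    n = 0
    with open(path, "w", encoding="utf-8") as fh:
        for p in posts:
            fh.write(
                json.dumps(
                    {"user_id": p.user_id, "timestamp": _iso(p.timestamp), "text": p.text},
                    ensure_ascii=False,
                )
                + "\n"
            )
            n += 1
    return n


def read_posts(path: str | Path) -> list[Post]:
    posts = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            if not line.strip():
                continue
            d = json.loads(line)
            posts.append(
                Post(user_id=d["user_id"], timestamp=_parse_ts(d["timestamp"]), text=d["text"])
            )
    return posts


def write_surveys(path: str | Path, surveys: Sequence[SurveyObservation]) -> int:
    rows = []
    for s in surveys:
        row = {"user_id": s.user_id, "date": s.date.isoformat(), "si": s.si, "scale": s.scale}
        for c in _COVARIATES:
            row[c] = s.covariates.get(c, "")
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)
    return len(rows)


def read_surveys(path: str | Path) -> list[SurveyObservation]:
    df = pd.read_csv(path)
    out = []
    for _, r in df.iterrows():
        covs = {
            c: float(r[c])
            for c in _COVARIATES
            if c in df.columns and pd.notna(r[c]) and r[c] != ""
        }
        out.append(
            SurveyObservation(
                user_id=str(r["user_id"]),
                date=_dt.date.fromisoformat(str(r["date"])),
                si=int(r["si"]),
                scale=str(r["scale"]),
                covariates=covs,
            )
        )
    return out


def write_mentions(path: str | Path, events: Sequence[MentionEvent]) -> int:
    with open(path, "w", encoding="utf-8") as fh:
        for ev in events:
            fh.write(
                json.dumps(
                    {
                        "user_id": ev.user_id,
                        "event_id": ev.event_id,
                        "mention_ts": _iso(ev.mention_ts),
                        "responses": [
                            {
                                "ts": _iso(r.ts),
                                "responder_id": r.responder_id,
                                "text": r.text,
                                "is_retweet": r.is_retweet,
                            }
                            for r in ev.responses
                        ],
                    },
                    ensure_ascii=False,
                )
                + "\n"
            )
    return len(events)


def read_mentions(path: str | Path) -> list[MentionEvent]:
    events = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            if not line.strip():
                continue
            d = json.loads(line)
            events.append(
                MentionEvent(
                    user_id=d["user_id"],
                    event_id=d.get("event_id", ""),
                    mention_ts=_parse_ts(d["mention_ts"]),
                    responses=tuple(
                        Response(
                            ts=_parse_ts(r["ts"]),
                            responder_id=r["responder_id"],
                            text=r["text"],
                            is_retweet=bool(r.get("is_retweet", False)),
                        )
                        for r in d["responses"]
                    ),
                )
            )
    return events


def write_daily_scores(path: str | Path, series_by_user: Mapping[str, DailyScoreSeries]) -> int:
    rows = []
    for uid in sorted(series_by_user):
        f = series_by_user[uid].frame
        for d, r in f.iterrows():
            rows.append(
                {
                    "user_id": uid,
                    "date": d.isoformat(),
                    "mean_score": float(r["mean_score"]),
                    "post_count": int(r["post_count"]),
                }
            )
    pd.DataFrame(rows).to_csv(path, index=False)
    return len(rows)


def read_daily_scores(path: str | Path) -> dict[str, DailyScoreSeries]:
    df = pd.read_csv(path)
    out: dict[str, DailyScoreSeries] = {}
    for uid, sub in df.groupby("user_id", sort=True):
        days = [_dt.date.fromisoformat(str(d)) for d in sub["date"]]
        out[str(uid)] = DailyScoreSeries.from_days(
            str(uid), days, sub["mean_score"].tolist(), sub["post_count"].tolist()
        )
    return out


def write_truth(path: str | Path, truth: Mapping) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(truth, fh, indent=1, sort_keys=True, default=str)


def read_truth(path: str | Path) -> dict:
    with open(path, encoding="utf-8") as fh:
        return json.load(fh)
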