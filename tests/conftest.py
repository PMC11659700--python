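import datetime as dt

import numpy as np
import pytest

from sitraj.scoring import DailyScoreSeries, Post

UTC = dt.timezone.utc


def make_posts(user_id, day_texts, start=dt.date(2020, 1, 1)):
    """day_texts: list of (day_offset, text) -> Post list with noon timestamps."""
    posts = []
    for i, (d, text) in enumerate(day_texts):
        ts = dt.datetime.combine(start, dt.time(12, 0), tzinfo=UTC) + dt.timedelta(
            days=d, seconds=i
        )
        posts.append(Post(user_id=user_id, timestamp=ts, text=text))
    return posts


def make_series(user_id, values, start=dt.date(2020, 1, 1), counts=None):
    """Series over consecutive days; None values are gaps."""
    days, scores, ns = [], [], []
    for d, v in enumerate(values):
        if v is None:
            continue
        days.append(start + dt.timedelta(days=d))
        scores.append(v)
        ns.append(counts[d] if counts is not None else 3)
    return DailyScoreSeries.from_days(user_id, days, scores, ns)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def start_date():
    return dt.date(2020, 1, 1)
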