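"""Word and bigram overrepresentation between two response corpora.

Responses are compared at the level of *presence* — does a response
contain the token at least once — not raw frequency, so verbose
responses do not dominate.  "Co-occurring word pairs" are adjacent
bigrams after tokenization.  Each token's 2x2 presence table
(containing vs not, corpus A vs B) is tested with a two-tailed Fisher
exact test, appropriate at the corpus sizes typical of response data
(tens to a few hundred responses); a chi-square variant is available.
No multiplicity correction by default; a Benjamini-Hochberg flag is
provided.
"""

from __future__ import annotations

import warnings
from typing import Callable, Literal, Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.stats as sps

from .association import bh_adjust
from .errors import ConfigurationError, InputError
from .scoring import tokenize

__all__ = ["corpus_counts", "enrichment_test"]

Unit = Literal["word", "bigram"]


def _units(tokens: list[str], unit: Unit) -> set[str]:
    if unit == "word":
        return set(tokens)
    return {f"{a} {b}" for a, b in zip(tokens, tokens[1:])}


def corpus_counts(
    responses: Sequence[str],
    unit: Unit = "word",
    tokenizer: Callable[[str], list[str]] = tokenize,
) -> dict[str, tuple[int, int]]:
    """Per-token document counts: token -> (responses containing it, total responses).

    Presence/absence per response, not raw frequency.  Responses that
    tokenize to nothing are skipped with a warning and excluded from
    the total.
    """
    if len(responses) == 0:
        raise InputError("responses must be nonempty")
    if unit not in ("word", "bigram"):
        raise ConfigurationError(f"unit must be 'word' or 'bigram', got {unit!r}")
    counts: dict[str, int] = {}
    total = 0
    skipped = 0
    for text in responses:
        toks = tokenizer(text)
        if not toks:
            skipped += 1
            continue
        total += 1
        for u in _units(toks, unit):
            counts[u] = counts.get(u, 0) + 1
    if skipped:
        warnings.warn(f"skipped {skipped} responses with no tokens", stacklevel=2)
    return {tok: (k, total) for tok, k in counts.items()}


def enrichment_test(
    counts_a: Mapping[str, tuple[int, int]],
    counts_b: Mapping[str, tuple[int, int]],
    unit: Unit = "word",
    min_count: int = 5,
    method: Literal["fisher", "chi2"] = "fisher",
    bh_correct: bool = False,
) -> pd.DataFrame:
    """Test each token for differential presence between corpora A and B.

    Tokens appearing at least ``min_count`` times overall enter the
    test; each gets a two-tailed p from its 2x2 presence table and an
    odds ratio (inf when only B lacks carriers).  Rows are sorted by p.
    Saturated or empty tables yield odds ratio 1, p = 1 and are
    retained.
    """
    if not counts_a or not counts_b:
        raise InputError("both corpora must be nonempty")
    total_a = next(iter(counts_a.values()))[1]
    total_b = next(iter(counts_b.values()))[1]
    tokens = set(counts_a) | set(counts_b)
    rows = []
    for tok in sorted(tokens):
        ca = counts_a.get(tok, (0, total_a))[0]
        cb = counts_b.get(tok, (0, total_b))[0]
        if ca + cb < min_count:
            continue
        table = np.array([[ca, total_a - ca], [cb, total_b - cb]])
        if (ca == total_a and cb == total_b) or (ca == 0 and cb == 0):
            # zero-variance presence column: no information either way
            odds, p = 1.0, 1.0
        elif method == "fisher":
            odds, p = sps.fisher_exact(table, alternative="two-sided")
        elif method == "chi2":
            chi2, p, _, _ = sps.chi2_contingency(table, correction=True)
            with np.errstate(divide="ignore", invalid="ignore"):
                odds = (ca * (total_b - cb)) / ((total_a - ca) * cb) if (total_a - ca) * cb else np.inf
        else:
            raise ConfigurationError(f"unknown method {method!r}")
        rows.append(
            {
                "unit": unit,
                "token": tok,
                "count_a": int(ca),
                "total_a": int(total_a),
                "count_b": int(cb),
                "total_b": int(total_b),
                "odds_ratio": float(odds),
                "p_value": float(p),
            }
        )
    df = pd.DataFrame(rows)
    if df.empty:
        return df
    if bh_correct:
        df["p_adjusted"] = bh_adjust(df["p_value"].to_numpy())
    return df.sort_values(["p_value", "token"], kind="stable").reset_index(drop=True)
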