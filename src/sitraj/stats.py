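"""Shared statistical helpers.

Only the pieces that need non-default behavior live here; everything
else is delegated to scipy/statsmodels at the call site.
"""

from __future__ import annotations

import itertools
from typing import NamedTuple, Sequence

import numpy as np
import scipy.stats as sps

__all__ = ["SpearmanResult", "spearman"]


class SpearmanResult(NamedTuple):
    rho: float
    p: float
    n: int


def _rank_corr(rx: np.ndarray, ry: np.ndarray) -> float:
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    denom = np.sqrt((rx @ rx) * (ry @ ry))
    if denom == 0:
        return float("nan")
    return float((rx @ ry) / denom)


def spearman(x: Sequence[float], y: Sequence[float]) -> SpearmanResult:
    """Spearman rank correlation with a two-tailed p-value.

    Ties receive average ranks.  For n >= 10 the p-value uses the
    classical t approximation ``t = rho * sqrt((n-2)/(1-rho^2))``; below
    10 it is computed exactly by enumerating all n! permutations of one
    variable (the permutation null of the rank statistic, valid with
    ties).  Zero variance in either variable yields rho = NaN, p = NaN.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have the same length")
    n = len(x)
    if n < 3:
        return SpearmanResult(float("nan"), float("nan"), n)
    rx = sps.rankdata(x)
    ry = sps.rankdata(y)
    rho = _rank_corr(rx, ry)
    if np.isnan(rho):
        return SpearmanResult(float("nan"), float("nan"), n)
    if n >= 10:
        if abs(rho) >= 1.0:
            return SpearmanResult(rho, 0.0, n)
        t = rho * np.sqrt((n - 2) / (1 - rho * rho))
        p = 2 * sps.t.sf(abs(t), df=n - 2)
        return SpearmanResult(rho, float(min(p, 1.0)), n)
    perms = np.array(list(itertools.permutations(range(n))))
    ry_perm = ry[perms]  # (n!, n)
    rxc = rx - rx.mean()
    ryc = ry_perm - ry_perm.mean(axis=1, keepdims=True)
    denom = np.sqrt((rxc @ rxc) * (ryc * ryc).sum(axis=1))
    with np.errstate(invalid="ignore", divide="ignore"):
        rhos = (ryc @ rxc) / denom
    hits = int(np.sum(np.abs(rhos) >= abs(rho) - 1e-12))
    return SpearmanResult(rho, hits / len(perms), n)
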