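"""Slope pairs, slope-interaction model, gap-threshold scan, Spearman."""

import datetime as dt
import itertools
import math

import numpy as np
import pytest

from sitraj.association import SurveyObservation
from sitraj.errors import ClassError, InputError, SingularDesignError, WindowError
from sitraj.stats import spearman
from sitraj.trajectory import (
    SlopePair,
    build_slope_pairs,
    event_aligned_comparison,
    gap_threshold_scan,
    slope_interaction_model,
)

from conftest import make_series

D0 = dt.date(2020, 1, 1)


def survey(uid, day, si):
    return SurveyObservation(uid, D0 + dt.timedelta(days=day), si)


def brute_spearman_rho(x, y):
    """Average-rank formula: Pearson correlation of midranks."""

    def midranks(v):
        order = sorted(range(len(v)), key=lambda i: v[i])
        ranks = [0.0] * len(v)
        i = 0
        while i < len(order):
            j = i
            while j + 1 < len(order) and v[order[j + 1]] == v[order[i]]:
                j += 1
            r = (i + j) / 2 + 1
            for k in range(i, j + 1):
                ranks[order[k]] = r
            i = j + 1
        return ranks

    rx, ry = midranks(list(x)), midranks(list(y))
    mx, my = np.mean(rx), np.mean(ry)
    num = sum((a - mx) * (b - my) for a, b in zip(rx, ry))
    den = math.sqrt(sum((a - mx) ** 2 for a in rx) * sum((b - my) ** 2 for b in ry))
    return num / den


class TestSpearman:
    def test_matches_rank_formula_with_ties(self, rng):
        for _ in range(15):
            n = int(rng.integers(4, 25))
            x = rng.choice([1.0, 2.0, 3.0, 5.0], size=n)
            y = rng.normal(size=n)
            res = spearman(x, y)
            if np.ptp(x) == 0:
                assert np.isnan(res.rho)
            else:
                assert res.rho == pytest.approx(brute_spearman_rho(x, y))

    def test_exact_small_n_p_by_enumeration(self):
        x = [1.0, 2.0, 3.0, 4.0, 5.0, 6.0]
        y = [2.0, 1.0, 4.0, 3.0, 6.0, 5.0]
        res = spearman(x, y)
        # independent enumeration over all 720 permutations of y
        obs = abs(brute_spearman_rho(x, y))
        hits = sum(
            abs(brute_spearman_rho(x, perm)) >= obs - 1e-12
            for perm in itertools.permutations(y)
        )
        assert res.p == pytest.approx(hits / math.factorial(6))

    def test_monotone_sequence(self):
        res = spearman(np.arange(12.0), np.arange(12.0) ** 3)
        assert res.rho == pytest.approx(1.0)
        assert res.p == pytest.approx(0.0, abs=1e-12)


class TestBuildSlopePairs:
    def test_si_difference_quotient(self):
        series = {"u": make_series("u", list(np.linspace(0.3, 0.5, 11)))}
        pairs = build_slope_pairs(series, [survey("u", 0, 1), survey("u", 10, 3)])
        assert len(pairs) == 1
        assert pairs[0].si_slope == pytest.approx(0.2)
        assert pairs[0].delta_days == 10

    def test_exact_linear_scores_both_modes(self):
        vals = [0.3 + 0.01 * d for d in range(15)]
        series = {"u": make_series("u", vals)}
        surveys = [survey("u", 0, 0), survey("u", 14, 1)]
        for mode in ("all_days_between", "entry_days_only"):
            (pair,) = build_slope_pairs(series, surveys, mode=mode)
            assert pair.score_slope == pytest.approx(0.01)

    def test_all_days_slope_matches_normal_equations(self, rng):
        vals = list(rng.uniform(0.2, 0.8, 21))
        series = {"u": make_series("u", vals)}
        (pair,) = build_slope_pairs(series, [survey("u", 0, 0), survey("u", 20, 2)])
        x = np.arange(21.0)
        X = np.column_stack([np.ones(21), x])
        beta = np.linalg.solve(X.T @ X, X.T @ np.array(vals))
        assert pair.score_slope == pytest.approx(beta[1])

    def test_unsorted_dates_rejected(self):
        series = {"u": make_series("u", [0.5] * 20)}
        with pytest.raises(InputError):
            build_slope_pairs(series, [survey("u", 10, 1), survey("u", 0, 0)])
        with pytest.raises(InputError):
            build_slope_pairs(series, [survey("u", 5, 1), survey("u", 5, 0)])

    def test_translation_and_scale_equivariance(self, rng):
        vals = list(rng.uniform(0.2, 0.4, 15))
        series = {"u": make_series("u", vals)}
        surveys = [survey("u", 2, 0), survey("u", 12, 2)]
        (p1,) = build_slope_pairs(series, surveys)
        shifted = {"u": make_series("u", vals, start=D0 + dt.timedelta(days=50))}
        ssurv = [
            SurveyObservation("u", s.date + dt.timedelta(days=50), s.si) for s in surveys
        ]
        (p2,) = build_slope_pairs(shifted, ssurv)
        assert p2.score_slope == pytest.approx(p1.score_slope)
        doubled = {"u": make_series("u", [v * 2 for v in vals])}
        (p3,) = build_slope_pairs(doubled, surveys)
        assert p3.score_slope == pytest.approx(2 * p1.score_slope)


def _pairs_from(rng, n, coupling=0.0, deltas=None):
    pairs = []
    for i in range(n):
        delta = int(deltas[i]) if deltas is not None else int(rng.integers(5, 60))
        score_slope = rng.normal(0, 0.01)
        si_slope = coupling * delta * score_slope + rng.normal(0, 0.01)
        pairs.append(
            SlopePair(f"u{i}", D0, D0 + dt.timedelta(days=delta), delta,
                      si_slope, score_slope, "all_days_between")
        )
    return pairs


class TestSlopeInteractionModel:
    def test_collinear_delta_raises(self, rng):
        pairs = _pairs_from(rng, 20, deltas=[14] * 20)
        with pytest.raises(SingularDesignError):
            slope_interaction_model(pairs, method="ols")

    def test_recovers_interaction_sign(self, rng):
        hits = 0
        for rep in range(40):
            local = np.random.default_rng(rep)
            pairs = _pairs_from(local, 80, coupling=0.5)
            fit = slope_interaction_model(pairs, method="ols")
            hits += fit.beta_interaction > 0 and fit.p_interaction < 0.05
        assert hits >= 38  # strong planted signal recovered nearly always

    def test_null_calibration(self):
        rej = 0
        n_rep = 200
        for rep in range(n_rep):
            local = np.random.default_rng(10_000 + rep)
            pairs = _pairs_from(local, 60, coupling=0.0)
            fit = slope_interaction_model(pairs, method="ols")
            rej += fit.p_interaction < 0.05
        assert 0.02 <= rej / n_rep <= 0.08


class TestGapThresholdScan:
    def test_threshold_below_minimum_gap_missing(self, rng):
        pairs = _pairs_from(rng, 20, deltas=list(rng.integers(30, 60, 20)))
        scan = gap_threshold_scan(pairs, thresholds=[10, 20, 90])
        row10 = scan[scan.threshold == 10].iloc[0]
        assert np.isnan(row10["rho"]) and row10["reason"] == "fewer than 4 pairs"

    def test_constant_si_slope_missing(self, rng):
        pairs = [
            SlopePair(f"u{i}", D0, D0 + dt.timedelta(days=20), 20, 0.0,
                      float(rng.normal()), "all_days_between")
            for i in range(10)
        ]
        scan = gap_threshold_scan(pairs, thresholds=[30])
        assert scan.iloc[0]["reason"] == "zero variance"

    def test_large_threshold_equals_unthresholded(self, rng):
        pairs = _pairs_from(rng, 30, coupling=0.3)
        scan = gap_threshold_scan(pairs, thresholds=[10_000])
        si = [p.si_slope for p in pairs]
        sc = [p.score_slope for p in pairs]
        res = spearman(sc, si)
        assert scan.iloc[0]["rho"] == pytest.approx(res.rho)
        assert scan.iloc[0]["n"] == 30

    def test_localizes_short_gap_coupling(self):
        # coupling planted only for gaps <= 14 days
        hits = 0
        n_rep = 40
        for rep in range(n_rep):
            rng = np.random.default_rng(rep)
            pairs = []
            for i in range(120):
                delta = int(rng.integers(5, 80))
                score_slope = rng.normal(0, 0.01)
                si_slope = (3.0 * score_slope if delta <= 14 else 0.0) + rng.normal(0, 0.01)
                pairs.append(
                    SlopePair(f"u{i}", D0, D0 + dt.timedelta(days=delta), delta,
                              si_slope, score_slope, "all_days_between")
                )
            scan = gap_threshold_scan(pairs, thresholds=list(range(10, 101, 5)))
            ok = scan.dropna(subset=["rho"])
            best = ok.loc[ok["rho"].abs().idxmax(), "threshold"]
            hits += best <= 20
        assert hits >= 0.8 * n_rep


class TestEventAligned:
    def _series(self, rng, n, drift=0.0, event_day=30, n_days=60):
        out = {}
        for i in range(n):
            vals = 0.5 + rng.normal(0, 0.03, n_days)
            if drift:
                for d in range(event_day, n_days):
                    vals[d] += drift * (d - event_day)
            out[f"u{i}"] = make_series(f"u{i}", list(np.clip(vals, 0, 1)))
        return out

    def test_null_groups_rarely_diverge(self):
        rng = np.random.default_rng(3)
        series = self._series(rng, 40)
        groups = {f"u{i}": ("exposed" if i < 20 else "control") for i in range(40)}
        res = event_aligned_comparison(series, groups, D0 + dt.timedelta(days=30), 5, 5)
        assert (res["p"] < 0.05).mean() < 0.3

    def test_planted_post_event_drift_detected(self):
        rng = np.random.default_rng(4)
        exposed = self._series(rng, 25, drift=0.01)
        control = {}
        for i in range(25):
            vals = 0.5 + rng.normal(0, 0.03, 60)
            control[f"c{i}"] = make_series(f"c{i}", list(np.clip(vals, 0, 1)))
        series = {**exposed, **control}
        groups = {u: "exposed" for u in exposed} | {u: "control" for u in control}
        res = event_aligned_comparison(series, groups, D0 + dt.timedelta(days=30), 0, 20)
        late = res[res["day"] >= 10]
        assert (late["p"] < 0.05).mean() > 0.8
        assert (late["mean_exposed"] > late["mean_control"]).all()

    def test_degenerate_single_day_equals_plain_test(self):
        rng = np.random.default_rng(5)
        series = self._series(rng, 30)
        groups = {f"u{i}": ("exposed" if i < 15 else "control") for i in range(30)}
        day = D0 + dt.timedelta(days=10)
        res = event_aligned_comparison(series, groups, day, 0, 0)
        assert len(res) == 1
        import scipy.stats as sps

        a = [series[f"u{i}"].get(day) for i in range(15)]
        b = [series[f"u{i}"].get(day) for i in range(15, 30)]
        row = res.iloc[0]
        if row["test"] == "t":
            stat, p = sps.ttest_ind(a, b)
        else:
            stat, p = sps.mannwhitneyu(a, b, alternative="two-sided")
        assert row["p"] == pytest.approx(p)

    def test_missing_groups_raise(self, rng):
        series = self._series(np.random.default_rng(1), 4)
        with pytest.raises(ClassError):
            event_aligned_comparison(series, {"u0": "exposed"}, D0, 1, 1)

    def test_no_data_window_raises(self):
        rng = np.random.default_rng(2)
        series = self._series(rng, 6)
        groups = {f"u{i}": ("exposed" if i < 3 else "control") for i in range(6)}
        with pytest.raises(WindowError):
            event_aligned_comparison(series, groups, D0 + dt.timedelta(days=500), 2, 2)
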