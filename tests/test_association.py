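"""Interaction regression, sliding-window scan, AUC, permutation inference."""

import datetime as dt
import itertools

import numpy as np
import pandas as pd
import pytest

from sitraj.association import (
    SurveyObservation,
    bh_adjust,
    build_scan_rows,
    compute_auc,
    exhaustive_auc_pvalue,
    fit_interaction_model,
    normality_gate,
    permutation_auc_pvalue,
    regress_out,
    sliding_window_scan,
)
from sitraj.errors import (
    ClassError,
    DegenerateOutcomeError,
    InputError,
    SampleSizeError,
    SingularDesignError,
)
from sitraj.synthetic import simulate_interaction_rows

from conftest import make_series


def brute_force_auc(scores, labels):
    """Pair-counting oracle: P(case > control) + 0.5 P(tie)."""
    cases = [s for s, l in zip(scores, labels) if l == 1]
    controls = [s for s, l in zip(scores, labels) if l == 0]
    wins = sum((c > k) + 0.5 * (c == k) for c in cases for k in controls)
    return wins / (len(cases) * len(controls))


class TestInteractionModel:
    def test_exact_linear_data(self, rng):
        x1 = rng.uniform(0, 1, 40)
        x2 = rng.uniform(1, 5, 40)
        rows = pd.DataFrame(
            {"si": 0.1 + 0.2 * x1 * x2, "mean_score": x1, "mean_posts": x2}
        )
        fit = fit_interaction_model(rows)
        assert fit.beta_interaction == pytest.approx(0.2, abs=1e-10)
        assert fit.beta_main_score == pytest.approx(0.0, abs=1e-9)
        assert fit.beta_main_posts == pytest.approx(0.0, abs=1e-9)
        assert fit.df_num == 3
        assert fit.df_den == 40 - 3 - 1

    def test_constant_outcome_raises(self, rng):
        rows = pd.DataFrame(
            {"si": np.ones(20), "mean_score": rng.uniform(0, 1, 20),
             "mean_posts": rng.uniform(1, 5, 20)}
        )
        with pytest.raises(DegenerateOutcomeError):
            fit_interaction_model(rows)

    def test_too_few_rows(self):
        rows = pd.DataFrame({"si": [1, 2], "mean_score": [0.1, 0.2], "mean_posts": [1, 2]})
        with pytest.raises(SampleSizeError):
            fit_interaction_model(rows)

    def test_constant_predictor_raises(self, rng):
        rows = pd.DataFrame(
            {"si": rng.normal(size=20), "mean_score": rng.uniform(0, 1, 20),
             "mean_posts": np.full(20, 3.0)}
        )
        with pytest.raises(SingularDesignError):
            fit_interaction_model(rows)

    def test_affine_rescaling_equivariance(self, rng):
        rows = simulate_interaction_rows(80, 0.05, seed=3)
        fit = fit_interaction_model(rows)
        scaled = rows.copy()
        scaled["mean_score"] = rows["mean_score"] * 2.0
        fit2 = fit_interaction_model(scaled)
        # doubling x1 halves the interaction coefficient; p unchanged
        assert fit2.beta_interaction == pytest.approx(fit.beta_interaction / 2)
        assert fit2.p_interaction == pytest.approx(fit.p_interaction, rel=1e-8)
        assert fit2.f_stat == pytest.approx(fit.f_stat, rel=1e-8)

    def test_parameter_recovery_simulation(self):
        # planted interaction recovered without bias (spot check; the full
        # 500-cohort version lives in the acceptance suite)
        beta = 0.004
        est = [
            fit_interaction_model(simulate_interaction_rows(300, beta, seed=s)).beta_interaction
            for s in range(60)
        ]
        se = np.std(est, ddof=1) / np.sqrt(len(est))
        assert abs(np.mean(est) - beta) < 3 * se

    def test_robust_method_runs(self):
        rows = simulate_interaction_rows(100, 0.1, seed=1)
        fit = fit_interaction_model(rows, method="robust")
        assert fit.method == "robust"
        assert np.isnan(fit.f_stat)
        assert 0 <= fit.p_interaction <= 1


class TestAuc:
    @pytest.mark.parametrize(
        "scores,labels,expected",
        [
            ([0.9, 0.8, 0.1, 0.2], [1, 1, 0, 0], 1.0),
            ([0.5, 0.5, 0.5, 0.5], [1, 1, 0, 0], 0.5),
            ([0.7, 0.3, 0.5, 0.2], [1, 1, 0, 0], 0.75),  # 4-pair hand count
        ],
    )
    def test_examples(self, scores, labels, expected):
        assert compute_auc(scores, labels) == pytest.approx(expected)

    def test_one_class_raises(self):
        with pytest.raises(ClassError):
            compute_auc([0.1, 0.2], [1, 1])

    def test_matches_pair_counting_oracle(self, rng):
        for _ in range(20):
            n = int(rng.integers(6, 30))
            scores = rng.choice([0.1, 0.2, 0.3, 0.5, 0.9], size=n)  # force ties
            labels = rng.integers(0, 2, n)
            if labels.min() == labels.max():
                labels[0] = 1 - labels[0]
            assert compute_auc(scores, labels) == pytest.approx(
                brute_force_auc(scores, labels)
            )

    def test_negation_symmetry(self, rng):
        scores = rng.normal(size=50)
        labels = np.r_[np.ones(20, int), np.zeros(30, int)]
        assert compute_auc(scores, labels) + compute_auc(-scores, labels) == pytest.approx(1.0)


class TestPermutationAuc:
    def test_exhaustive_3v3(self, rng):
        scores = [0.9, 0.7, 0.4, 0.6, 0.2, 0.1]
        labels = [1, 1, 1, 0, 0, 0]
        exact = exhaustive_auc_pvalue(scores, labels)  # over all C(6,3)=20 splits
        res = permutation_auc_pvalue(scores, labels, n_perm=4000, seed=0)
        se = np.sqrt(exact * (1 - exact) / res.n_perm)
        assert abs(res.perm_p - exact) < 2 * se + 1 / res.n_perm

    def test_perfect_separation_tail(self):
        scores = np.r_[np.linspace(0.6, 0.9, 10), np.linspace(0.1, 0.4, 10)]
        labels = np.r_[np.ones(10, int), np.zeros(10, int)]
        res = permutation_auc_pvalue(scores, labels, n_perm=10_000, seed=1)
        assert res.auc == 1.0
        assert res.perm_p <= 0.001

    def test_deterministic_given_seed(self, rng):
        scores = rng.normal(size=40)
        labels = rng.integers(0, 2, 40)
        labels[:2] = [0, 1]
        a = permutation_auc_pvalue(scores, labels, n_perm=500, seed=9)
        b = permutation_auc_pvalue(scores, labels, n_perm=500, seed=9)
        assert a == b

    def test_null_calibration(self):
        # labels independent of scores: rejection rate near alpha (spot
        # check at 200 replicates; 500-replicate version in acceptance)
        rng = np.random.default_rng(77)
        rej = 0
        n_rep = 200
        for _ in range(n_rep):
            scores = rng.normal(size=60)
            labels = np.r_[np.ones(30, int), np.zeros(30, int)]
            rng.shuffle(labels)
            res = permutation_auc_pvalue(scores, labels, n_perm=400, seed=int(rng.integers(2**31)))
            rej += res.perm_p <= 0.05
        assert 0.02 <= rej / n_rep <= 0.08


class TestRegressOut:
    def test_perfect_fit_gives_zeros(self, rng):
        X = rng.normal(size=(30, 2))
        y = 1.5 + X @ np.array([2.0, -1.0])
        assert np.allclose(regress_out(y, X), 0.0)

    def test_orthogonal_covariate_centers_only(self):
        y = np.array([1.0, 2.0, 3.0, 4.0])
        x = np.array([1.0, -1.0, -1.0, 1.0])  # orthogonal to y - mean(y)
        out = regress_out(y, x.reshape(-1, 1))
        assert np.allclose(out, y - y.mean())

    def test_residuals_orthogonal_to_covariates(self, rng):
        X = rng.normal(size=(50, 3))
        y = rng.normal(size=50)
        resid = regress_out(y, X)
        assert abs(resid.mean()) < 1e-10
        assert np.allclose(X.T @ resid, 0.0, atol=1e-8)

    def test_fitted_removed_complement(self, rng):
        X = rng.normal(size=(20, 2))
        y = rng.normal(size=20)
        assert np.allclose(
            regress_out(y, X) + regress_out(y, X, keep="fitted_removed"), y
        )

    def test_rank_deficiency_raises(self, rng):
        x = rng.normal(size=20)
        X = np.column_stack([x, 2 * x])
        with pytest.raises(SingularDesignError):
            regress_out(rng.normal(size=20), X)


class TestNormalityGate:
    def test_normal_sample_mostly_parametric(self):
        rng = np.random.default_rng(5)
        calls = [normality_gate(rng.normal(size=500)) for _ in range(200)]
        assert calls.count("parametric") >= 0.90 * len(calls)

    def test_exponential_sample_nonparametric(self):
        rng = np.random.default_rng(6)
        calls = [normality_gate(rng.exponential(size=500)) for _ in range(100)]
        assert calls.count("nonparametric") >= 0.99 * len(calls)

    def test_constant_vector_nonparametric(self):
        assert normality_gate(np.ones(20)) == "nonparametric"

    def test_small_sample_raises(self):
        with pytest.raises(SampleSizeError):
            normality_gate(np.arange(5))


class TestSlidingWindowScan:
    def _toy(self, rng, n_users=30, n_days=30):
        series = {}
        surveys = []
        for i in range(n_users):
            uid = f"u{i}"
            series[uid] = make_series(uid, list(rng.uniform(0.2, 0.8, n_days)))
            surveys.append(
                SurveyObservation(uid, dt.date(2020, 1, 1) + dt.timedelta(days=n_days), int(rng.integers(0, 4)))
            )
        if len({s.si for s in surveys}) == 1:
            surveys[0] = SurveyObservation(surveys[0].user_id, surveys[0].date, 3)
        return series, surveys

    def test_deterministic(self, rng):
        series, surveys = self._toy(rng)
        a = sliding_window_scan(series, surveys, [1, 5, 10]).to_frame()
        b = sliding_window_scan(series, surveys, [1, 5, 10]).to_frame()
        pd.testing.assert_frame_equal(a, b)

    def test_empty_window_marked_missing(self, rng):
        series, surveys = self._toy(rng)
        # surveys dated far beyond the data: no day qualifies at window 1
        far = [
            SurveyObservation(s.user_id, s.date + dt.timedelta(days=400), s.si)
            for s in surveys
        ]
        scan = sliding_window_scan(series, far, [1])
        assert scan.fits[1] is None
        assert "no eligible rows" in scan.missing[1]

    def test_scan_continues_past_missing_windows(self, rng):
        series, surveys = self._toy(rng)
        scan = sliding_window_scan(series, surveys, [1, 10])
        assert set(scan.fits) == {1, 10}

    def test_rows_match_windowed_mean(self, rng):
        series, surveys = self._toy(rng, n_users=5)
        rows = build_scan_rows(series, surveys, 7)
        assert len(rows) == 5
        from sitraj.scoring import windowed_mean

        for _, r in rows.iterrows():
            ws = windowed_mean(series[r["user_id"]], r["date"], 7)
            assert r["mean_score"] == pytest.approx(ws.mean_score)


def test_bh_adjust_matches_enumerated_definition():
    p = [0.01, 0.04, 0.03, 0.8]
    adj = bh_adjust(p)
    m = 4
    expected = {}
    order = np.argsort(p)
    prev = 1.0
    for rank_from_end, idx in enumerate(order[::-1]):
        rank = m - rank_from_end
        val = min(p[idx] * m / rank, prev)
        expected[idx] = val
        prev = val
    assert np.allclose(adj, [expected[i] for i in range(m)])
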