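import numpy as np
import pytest

from etilscore.survival_stats import (
    SurvivalRecord,
    agreement,
    association_test,
    cox_multivariable,
    crossvalidate_cutpoint,
    find_cutpoint,
    km_curve,
    logrank_chi2,
    read_survival_csv,
    records_to_frame,
)
from etilscore.synthetic_data import CohortSpec, generate_cohort


# ---------------------------------------------------------------------------
# independent oracles

def brute_force_logrank(times, events, groups):
    """Risk-set table expansion, one event time at a time."""
    times = np.asarray(times, float)
    events = np.asarray(events, bool)
    groups = np.asarray(groups, bool)
    obs = exp = var = 0.0
    for t in sorted(set(times[events])):
        at_risk = times >= t
        n = at_risk.sum()
        d = (events & (times == t)).sum()
        n1 = (at_risk & groups).sum()
        d1 = (events & (times == t) & groups).sum()
        obs += d1
        exp += d * n1 / n
        if n > 1:
            var += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    chi2 = (obs - exp) ** 2 / var if var > 0 else 0.0
    return chi2


def newton_raphson_cox_binary(times, events, x):
    """Partial-likelihood Newton iteration for one binary covariate,
    distinct event times (no tie handling needed)."""
    times = np.asarray(times, float)
    events = np.asarray(events, bool)
    x = np.asarray(x, float)
    beta = 0.0
    for _ in range(50):
        u = 0.0
        info = 0.0
        for t in times[events]:
            risk = times >= t
            w = np.exp(beta * x[risk])
            xb = (w * x[risk]).sum() / w.sum()
            x2b = (w * x[risk] ** 2).sum() / w.sum()
            xi = x[(times == t) & events][0]
            u += xi - xb
            info += x2b - xb**2
        step = u / info
        beta += step
        if abs(step) < 1e-12:
            break
    return beta


def _records(times, events, scores=None, cov=None):
    n = len(times)
    scores = scores if scores is not None else np.zeros(n)
    return [
        SurvivalRecord(
            id=str(i),
            score=float(scores[i]),
            time_months=float(times[i]),
            event=bool(events[i]),
            covariates=dict(cov[i]) if cov else {},
        )
        for i in range(n)
    ]


class TestLogrank:
    def test_identical_groups_give_zero(self):
        times = [1, 2, 3, 1, 2, 3]
        events = [1, 1, 0, 1, 1, 0]
        groups = [0, 0, 0, 1, 1, 1]
        chi2, p = logrank_chi2(times, events, groups)
        assert chi2 == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_six_subject_worked_example_matches_bruteforce(self):
        times = [1, 2, 3, 4, 5, 6]
        events = [1, 1, 1, 1, 1, 1]
        groups = [1, 1, 1, 0, 0, 0]
        chi2, _ = logrank_chi2(times, events, groups)
        assert chi2 == pytest.approx(brute_force_logrank(times, events, groups), abs=1e-9)

    @pytest.mark.parametrize("seed", range(5))
    def test_random_cases_match_bruteforce(self, seed):
        rng = np.random.default_rng(seed)
        n = 40
        times = rng.exponential(30, n).round(1)  # rounding forces ties
        events = rng.random(n) < 0.7
        groups = rng.random(n) < 0.5
        if events.sum() == 0 or groups.all() or not groups.any():
            pytest.skip("degenerate draw")
        chi2, _ = logrank_chi2(times, events, groups)
        assert chi2 == pytest.approx(brute_force_logrank(times, events, groups), abs=1e-9)

    def test_matches_lifelines(self):
        from lifelines.statistics import logrank_test

        rng = np.random.default_rng(1)
        times = rng.exponential(40, 120)
        events = rng.random(120) < 0.8
        groups = rng.random(120) < 0.4
        chi2, p = logrank_chi2(times, events, groups)
        ref = logrank_test(times[groups], times[~groups], events[groups], events[~groups])
        assert chi2 == pytest.approx(ref.test_statistic, abs=1e-9)
        assert p == pytest.approx(ref.p_value, abs=1e-12)

    def test_group_relabeling_invariance(self):
        rng = np.random.default_rng(2)
        times = rng.exponential(40, 60)
        events = rng.random(60) < 0.7
        groups = rng.random(60) < 0.5
        a, _ = logrank_chi2(times, events, groups)
        b, _ = logrank_chi2(times, events, ~groups)
        assert a == pytest.approx(b, abs=1e-12)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            logrank_chi2([1, 2], [1, 1], [0, 0])  # one group
        with pytest.raises(ValueError):
            logrank_chi2([1, 2], [0, 0], [0, 1])  # no events


class TestKaplanMeier:
    def test_no_events_stays_at_one(self):
        pairs = km_curve([5, 10, 15], [0, 0, 0])
        assert all(s == 1.0 for _, s in pairs)

    def test_censoring_worked_example(self):
        # event at 1, censored at 2, event at 3, by the product limit:
        # S(1) = 2/3; censoring at 2 leaves one subject at risk at t=3,
        # so S(3) = 2/3 * (1 - 1/1) = 0
        pairs = dict(km_curve([1, 2, 3], [1, 0, 1]))
        assert pairs[0.0] == pytest.approx(1.0)
        assert pairs[1.0] == pytest.approx(2 / 3)
        assert pairs[2.0] == pytest.approx(2 / 3)
        assert pairs[3.0] == pytest.approx(0.0)

    def test_all_events_closed_form(self):
        n = 8
        times = np.arange(1, n + 1)
        pairs = dict(km_curve(times, np.ones(n)))
        for k, t in enumerate(times, start=1):
            assert pairs[float(t)] == pytest.approx((n - k) / n)


class TestCutpoint:
    def test_all_identical_scores_rejected(self):
        rng = np.random.default_rng(0)
        recs = _records(rng.exponential(30, 30), np.ones(30), scores=np.full(30, 5.0))
        with pytest.raises(ValueError, match="no candidate"):
            find_cutpoint(recs)

    def test_minimum_size_preconditions(self):
        rng = np.random.default_rng(0)
        with pytest.raises(ValueError):
            find_cutpoint(_records(rng.exponential(30, 10), np.ones(10),
                                   scores=rng.uniform(0, 100, 10)))

    def test_profile_counts_admissible_gaps(self):
        """Profile length = number of distinct-score gaps passing the
        group-size constraint."""
        rng = np.random.default_rng(3)
        n = 50
        scores = rng.uniform(0, 100, n)
        recs = _records(rng.exponential(30, n), rng.random(n) < 0.8, scores=scores)
        res = find_cutpoint(recs, min_group_fraction=0.1)
        distinct = np.sort(np.unique(scores))
        mids = (distinct[:-1] + distinct[1:]) / 2
        admissible = [
            m for m in mids
            if min((scores > m).sum(), (scores <= m).sum()) >= 0.1 * n
        ]
        assert len(res.candidate_profile) == len(admissible)
        assert res.chi2_max == max(c for _, c in res.candidate_profile)
        assert any(res.threshold == m for m, _ in res.candidate_profile)

    def test_profile_chi2_matches_direct_logrank(self):
        rng = np.random.default_rng(4)
        n = 40
        scores = rng.uniform(0, 100, n)
        times = rng.exponential(30, n)
        events = rng.random(n) < 0.8
        res = find_cutpoint(_records(times, events, scores=scores))
        for cut, chi2 in res.candidate_profile[::5]:
            direct, _ = logrank_chi2(times, events, scores > cut)
            assert chi2 == pytest.approx(direct, abs=1e-9)

    def test_order_invariance(self):
        recs, _ = generate_cohort(CohortSpec(n=100, seed=9))
        res = find_cutpoint(recs)
        rng = np.random.default_rng(0)
        shuffled = [recs[i] for i in rng.permutation(len(recs))]
        res2 = find_cutpoint(shuffled)
        assert res2.threshold == res.threshold
        assert res2.chi2_max == pytest.approx(res.chi2_max, abs=1e-12)

    def test_strong_effect_detected_by_crossvalidation(self):
        recs, _ = generate_cohort(
            CohortSpec(n=200, true_threshold=25.0, hazard_ratio_high_vs_low=0.3, seed=12)
        )
        p = crossvalidate_cutpoint(recs, n_splits=50, seed=0)
        assert p < 0.05

    def test_single_split_degenerate_case(self):
        recs, _ = generate_cohort(CohortSpec(n=100, seed=5))
        p = crossvalidate_cutpoint(recs, n_splits=1, train_fraction=0.5, seed=0)
        assert 0.0 <= p <= 1.0


class TestCox:
    def test_binary_covariate_matches_newton_raphson_oracle(self):
        times = [2, 4, 6, 8, 10, 12, 14, 16]
        events = [1, 1, 1, 1, 1, 1, 1, 1]
        x = [1, 0, 1, 0, 1, 0, 0, 1]
        recs = _records(times, events, cov=[{"x": xi} for xi in x])
        out = cox_multivariable(recs, ["x"])
        beta_ref = newton_raphson_cox_binary(times, events, x)
        assert np.log(out.loc[0, "HR"]) == pytest.approx(beta_ref, abs=1e-6)

    def test_zero_events_rejected(self):
        recs = _records([1, 2, 3, 4], [0, 0, 0, 0], cov=[{"x": i % 2} for i in range(4)])
        with pytest.raises(ValueError, match="at least one event"):
            cox_multivariable(recs, ["x"])

    def test_constant_covariate_rejected(self):
        recs = _records([1, 2, 3, 4], [1, 1, 1, 1], cov=[{"x": 1.0}] * 4)
        with pytest.raises(ValueError, match="constant"):
            cox_multivariable(recs, ["x"])

    def test_categorical_covariates_one_hot_encoded(self):
        recs, _ = generate_cohort(CohortSpec(n=150, seed=2))
        out = cox_multivariable(recs, ["age", "sex", "stage"])
        assert set(out["covariate"]) == {"age", "sex_male", "stage"}
        assert np.all(out["ci_low"] <= out["HR"])
        assert np.all(out["HR"] <= out["ci_high"])

    def test_null_covariate_ci_covers_one(self):
        """Independent covariate: 95% CI covers HR=1 at ~nominal rate."""
        covered = 0
        reps = 100
        for rep in range(reps):
            rng = np.random.default_rng(rep)
            n = 150
            times = rng.exponential(50, n)
            events = rng.random(n) < 0.8
            x = rng.normal(size=n)
            recs = _records(times, events, cov=[{"x": float(v)} for v in x])
            out = cox_multivariable(recs, ["x"])
            covered += out.loc[0, "ci_low"] <= 1.0 <= out.loc[0, "ci_high"]
        assert 0.89 <= covered / reps <= 1.0

    def test_few_events_warns(self):
        recs, _ = generate_cohort(CohortSpec(n=30, seed=3, censoring_window_months=30))
        with pytest.warns(UserWarning, match="events"):
            cox_multivariable(recs, ["age", "stage", "ulceration", "tumor_depth"])


class TestAssociationAndAgreement:
    def test_mann_whitney_exact_enumeration_example(self):
        u, p = association_test([1, 2, 3, 4, 5, 6], [0, 0, 0, 1, 1, 1])
        assert u == 0.0
        assert p == pytest.approx(0.1, abs=1e-12)

    def test_all_tied_scores_give_nan_sentinel(self):
        u, p = association_test([5, 5, 5, 5], [0, 0, 1, 1])
        assert np.isnan(p)

    def test_identical_series_perfect_agreement(self):
        a = [10.0, 20.0, 30.0, 40.0, 50.0]
        icc, p = agreement(a, a)
        assert icc == pytest.approx(1.0)
        assert np.isnan(p)

    def test_constant_shift_lowers_icc_and_wilcoxon_detects(self):
        a = np.array([5.0, 12.0, 20.0, 31.0, 40.0, 55.0, 63.0, 70.0])
        icc, p = agreement(a, a + 10.0)
        assert icc < 1.0
        # signed-rank on 8 equal-sign differences: two-sided p = 2/2^8
        assert p == pytest.approx(2 / 256, abs=1e-9)

    def test_icc_matches_pingouin(self):
        import pandas as pd
        import pingouin as pg

        rng = np.random.default_rng(6)
        a = rng.uniform(0, 100, 12)
        b = a + rng.normal(0, 8, 12)
        icc, _ = agreement(a, b)
        long = pd.DataFrame({
            "targets": np.repeat(np.arange(12), 2),
            "raters": np.tile(["a", "b"], 12),
            "score": np.column_stack([a, b]).ravel(),
        })
        ref = pg.intraclass_corr(long, targets="targets", raters="raters", ratings="score")
        icc2 = ref.loc[ref["Type"] == "ICC(A,1)", "ICC"].iloc[0]
        assert icc == pytest.approx(icc2, abs=1e-9)

    def test_unequal_or_short_series_rejected(self):
        with pytest.raises(ValueError):
            agreement([1, 2], [1, 2])
        with pytest.raises(ValueError):
            agreement([1, 2, 3], [1, 2])


class TestIO:
    def test_survival_csv_round_trip(self, tmp_path):
        recs, _ = generate_cohort(CohortSpec(n=25, seed=8))
        df = records_to_frame(recs)
        path = tmp_path / "cohort.csv"
        df.to_csv(path, index=False)
        back = read_survival_csv(path)
        assert len(back) == 25
        assert back[0].id == recs[0].id
        assert back[0].score == pytest.approx(recs[0].score)
        assert back[0].covariates["sex"] == recs[0].covariates["sex"]

    def test_missing_columns_rejected(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("id,score\n1,2\n")
        with pytest.raises(ValueError, match="missing columns"):
            read_survival_csv(path)
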