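"""Survival statistics against hand-worked and brute-force oracles."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import hypergeom

from diastolica.errors import (
    BootstrapError,
    ConcordanceError,
    DegeneracyError,
    DegenerateSplitError,
    ParameterError,
)
from diastolica.survival import (
    bootstrap_ci,
    compare_descriptives,
    cox_partial_loglik,
    fit_cox,
    harrell_c,
    kaplan_meier,
    median_dichotomize,
    stepwise_bic,
)


def brute_force_efron_loglik(beta, X, times, events):
    """Independent evaluation of the Efron partial log-likelihood.

    Written directly from the formula: for each distinct event time with
    tied-death set D (|D| = d) and risk set R,
    ``sum_{i in D} eta_i - sum_{l=0}^{d-1} log(sum_R e^eta - (l/d) sum_D e^eta)``.
    """
    eta = np.asarray(X, dtype=float) @ np.atleast_1d(beta)
    ll = 0.0
    for t in sorted(set(times[events == 1])):
        D = [i for i in range(len(times)) if times[i] == t and events[i] == 1]
        R = [i for i in range(len(times)) if times[i] >= t]
        d = len(D)
        sum_r = sum(np.exp(eta[j]) for j in R)
        sum_d = sum(np.exp(eta[j]) for j in D)
        ll += sum(eta[j] for j in D)
        for l in range(d):
            ll -= np.log(sum_r - (l / d) * sum_d)
    return ll


def _sim_two_group(rng, n, hr, p=0.5, horizon=2.5):
    x = (rng.random(n) < p).astype(float)
    t = rng.exponential(5.0, n) / np.exp(np.log(hr) * x)
    events = (t <= horizon).astype(int)
    return pd.DataFrame({"x": x}), np.minimum(t, horizon), events


class TestMedianDichotomize:
    def test_hand_example(self):
        cutoff, ind = median_dichotomize([1, 2, 3])
        assert cutoff == 2
        assert ind.tolist() == [0, 0, 1]

    def test_degenerate(self):
        with pytest.raises(DegenerateSplitError):
            median_dichotomize([5, 5, 5])

    def test_nt_probnp_cutoff_near_anchor(self, rng):
        """The sample median of 1e4 NT-proBNP draws sits within 10% of the
        123.6 pg/mL population anchor."""
        from diastolica.cohort import CohortConfig

        draws = CohortConfig().covariate_specs["nt_probnp_pg_ml"].sample(rng, 10_000)
        cutoff, _ = median_dichotomize(draws)
        assert abs(cutoff - 123.6) / 123.6 < 0.10

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(
        st.lists(
            st.floats(min_value=-1e6, max_value=1e6, allow_nan=False),
            min_size=3,
            max_size=50,
        )
    )
    def test_indicator_is_strictly_above_cutoff(self, values):
        if np.all(np.asarray(values) == values[0]):
            return
        cutoff, ind = median_dichotomize(values)
        assert np.array_equal(ind, (np.asarray(values) > cutoff).astype(int))
        assert 0 < ind.sum() < len(values) or np.median(values) == max(values)


class TestKaplanMeier:
    def test_product_limit_hand_example(self):
        """times [1,2,3,4], events [1,1,1,0]: S = 0.75, 0.50, 0.25."""
        km = kaplan_meier(np.array([1.0, 2.0, 3.0, 4.0]), np.array([1, 1, 1, 0]))
        assert km.event_times.tolist() == [1.0, 2.0, 3.0]
        assert np.allclose(km.survival_probabilities, [0.75, 0.5, 0.25])
        assert km.at_risk.tolist() == [4.0, 3.0, 2.0]

    def test_all_censored_flat_curve(self):
        km = kaplan_meier(np.array([1.0, 2.0, 3.0]), np.array([0, 0, 0]))
        assert len(km.event_times) == 0  # S stays at 1 throughout

    def test_no_censoring_matches_empirical_survivor(self, rng):
        times = rng.exponential(2.0, 200).round(3) + 1e-3
        events = np.ones(200, dtype=int)
        km = kaplan_meier(times, events)
        for t, s in zip(km.event_times, km.survival_probabilities):
            assert s == pytest.approx(np.mean(times > t), abs=1e-12)

    def test_monotone_non_increasing(self, rng):
        times = rng.exponential(2.0, 300) + 1e-3
        events = rng.integers(0, 2, 300)
        km = kaplan_meier(times, events)
        assert np.all(np.diff(km.survival_probabilities) <= 1e-12)

    def test_validation(self):
        with pytest.raises(ParameterError):
            kaplan_meier(np.array([1.0, -1.0]), np.array([1, 0]))


class TestCox:
    def test_loglik_matches_brute_force(self, rng):
        """Fitted Efron log partial likelihood equals an independent
        brute-force evaluation on n <= 8 data, including ties."""
        times = np.array([1.0, 1.0, 2.0, 3.0, 3.0, 4.0, 5.0, 6.0])
        events = np.array([1, 1, 1, 0, 1, 1, 0, 1])
        X = pd.DataFrame({"x": rng.normal(size=8)})
        fit = fit_cox(X, times, events)
        oracle = brute_force_efron_loglik(
            fit.coefficients, X.to_numpy(), times, events
        )
        assert fit.log_partial_likelihood == pytest.approx(oracle, abs=1e-10)

    def test_fixed_lp_loglik_matches_brute_force(self, rng):
        times = np.array([1.0, 2.0, 2.0, 2.0, 3.0, 4.0, 5.0])
        events = np.array([1, 1, 1, 0, 1, 0, 1])
        x = rng.normal(size=7)
        beta = 0.7
        ours = cox_partial_loglik(beta * x, times, events)
        oracle = brute_force_efron_loglik([beta], x[:, None], times, events)
        assert ours == pytest.approx(oracle, abs=1e-12)

    def test_recovers_true_hazard_ratio(self, rng):
        X, t, e = _sim_two_group(rng, 2000, hr=2.0)
        fit = fit_cox(X, t, e)
        assert 1.8 <= fit.hazard_ratios[0] <= 2.2
        assert fit.p_values[0] < 1e-6

    def test_null_covariate(self, rng):
        X, t, e = _sim_two_group(rng, 2000, hr=1.0)
        fit = fit_cox(X, t, e)
        assert 0.85 <= fit.hazard_ratios[0] <= 1.18

    def test_constant_covariate_rejected(self):
        X = pd.DataFrame({"x": np.ones(50)})
        with pytest.raises(DegeneracyError):
            fit_cox(X, np.arange(1.0, 51.0), np.ones(50, dtype=int))

    def test_no_events_rejected(self, rng):
        X = pd.DataFrame({"x": rng.normal(size=20)})
        with pytest.raises(DegeneracyError):
            fit_cox(X, np.arange(1.0, 21.0), np.zeros(20, dtype=int))

    def test_hr_within_ci(self, rng):
        X, t, e = _sim_two_group(rng, 500, hr=2.0)
        fit = fit_cox(X, t, e)
        assert fit.ci_lower[0] <= fit.hazard_ratios[0] <= fit.ci_upper[0]


class TestBootstrap:
    def test_constant_data_degenerate_interval(self):
        data = pd.DataFrame({"x": np.full(30, 4.2)})
        lo, hi = bootstrap_ci(lambda d: d["x"].mean(), data, B=100, seed=0)
        assert lo == hi == pytest.approx(4.2)

    def test_exactly_B_resamples(self):
        calls = []
        data = pd.DataFrame({"x": np.arange(20.0)})
        bootstrap_ci(lambda d: calls.append(1) or d["x"].mean(), data, B=1000, seed=0)
        assert len(calls) == 1000

    def test_seeded_reproducibility(self):
        data = pd.DataFrame({"x": np.random.default_rng(5).normal(size=100)})
        a = bootstrap_ci(lambda d: d["x"].mean(), data, B=200, seed=42)
        b = bootstrap_ci(lambda d: d["x"].mean(), data, B=200, seed=42)
        assert a == b

    def test_failure_rate_guard(self):
        data = pd.DataFrame({"x": np.arange(10.0)})

        def flaky(d):
            raise RuntimeError("no statistic")

        with pytest.raises(BootstrapError):
            bootstrap_ci(flaky, data, B=50, seed=0)

    def test_mean_coverage(self, rng):
        """~95% of percentile intervals for the mean cover the truth."""
        hits = 0
        reps = 400
        for i in range(reps):
            data = pd.DataFrame({"x": rng.normal(size=200)})
            lo, hi = bootstrap_ci(lambda d: d["x"].mean(), data, B=200, seed=i)
            hits += lo <= 0.0 <= hi
        assert 0.90 <= hits / reps <= 0.98


class TestStepwiseBIC:
    def test_duplicate_candidates_one_retained(self, rng):
        X, t, e = _sim_two_group(rng, 800, hr=3.0)
        X = X.assign(x_copy=X["x"])
        model = stepwise_bic(X, t, e)
        assert model.selected == ("x",)

    def test_bic_trajectory_strictly_decreasing(self, rng):
        X, t, e = _sim_two_group(rng, 800, hr=3.0)
        X = X.assign(noise=rng.normal(size=800))
        model = stepwise_bic(X, t, e)
        assert np.all(np.diff(model.bic_trajectory) < 0)

    def test_all_noise_mostly_empty(self, rng):
        empty = 0
        for _ in range(15):
            X = pd.DataFrame(rng.normal(size=(1000, 3)), columns=list("abc"))
            t = rng.exponential(5.0, 1000)
            e = (t <= 2.5).astype(int)
            model = stepwise_bic(X, np.minimum(t, 2.5), e)
            empty += len(model.selected) == 0
        assert empty > 7

    def test_c_statistic_attached(self, rng):
        X, t, e = _sim_two_group(rng, 800, hr=3.0)
        model = stepwise_bic(X, t, e)
        assert model.final_fit is not None
        assert 0.5 < model.c_statistic <= 1.0


class TestHarrellC:
    def test_perfect_ranking(self):
        assert harrell_c([3, 2, 1], [1, 2, 3], [1, 1, 1]) == 1.0

    def test_reversed_ranking(self):
        assert harrell_c([1, 2, 3], [1, 2, 3], [1, 1, 1]) == 0.0

    def test_all_ties(self):
        assert harrell_c([2, 2, 2], [1, 2, 3], [1, 1, 1]) == 0.5

    def test_random_risks_near_half(self, rng):
        t = rng.exponential(2.0, 2000)
        e = (t <= 2.5).astype(int)
        c = harrell_c(rng.normal(size=2000), np.minimum(t, 2.5), e)
        assert c == pytest.approx(0.5, abs=0.03)

    def test_symmetry(self, rng):
        risks = rng.normal(size=100)
        t = rng.exponential(2.0, 100) + 1e-6
        e = rng.integers(0, 2, 100)
        e[0] = 1
        assert harrell_c(risks, t, e) + harrell_c(-risks, t, e) == pytest.approx(1.0)

    def test_matches_lifelines(self, rng):
        from lifelines.utils import concordance_index

        risks = rng.normal(size=300)
        t = rng.exponential(2.0, 300) + 1e-6  # continuous: no time ties
        e = rng.integers(0, 2, 300)
        ours = harrell_c(risks, t, e)
        theirs = concordance_index(t, -risks, e)
        assert ours == pytest.approx(theirs, abs=1e-12)

    def test_no_usable_pairs(self):
        with pytest.raises(ConcordanceError):
            harrell_c([1, 2], [1.0, 2.0], [0, 0])


class TestDescriptives:
    def test_fisher_matches_hypergeometric_enumeration(self):
        """Fisher's exact two-sided p for the 12/88 vs 8/2 comorbidity table
        equals the independent hypergeometric enumeration."""
        g0 = np.r_[np.ones(12), np.zeros(88)]
        g1 = np.r_[np.ones(8), np.zeros(2)]
        df = pd.DataFrame({"valvular": np.r_[g0, g1]})
        group = np.r_[np.zeros(100, bool), np.ones(10, bool)]
        table = compare_descriptives(df, group)
        p_fisher = table.loc[table["variable"] == "valvular", "p"].iloc[0]

        rv = hypergeom(110, 20, 100)  # N, total positives, alive margin
        p_obs = rv.pmf(12)
        p_enum = sum(
            rv.pmf(k) for k in range(10, 21) if rv.pmf(k) <= p_obs * (1 + 1e-9)
        )
        assert p_fisher == pytest.approx(p_enum, rel=1e-9)

    def test_identical_groups_p_near_one(self, rng):
        x = rng.normal(10, 2, 200)
        df = pd.DataFrame({"x": np.r_[x, x]})
        group = np.r_[np.zeros(200, bool), np.ones(200, bool)]
        table = compare_descriptives(df, group)
        assert table["p"].iloc[0] > 0.9

    def test_skewed_variable_routed_to_mannwhitney(self, rng):
        df = pd.DataFrame({"x": rng.lognormal(3, 1.5, 300)})
        group = rng.random(300) < 0.3
        table = compare_descriptives(df, group)
        assert table["test"].iloc[0] == "mann-whitney"
        assert "(" in table["group0"].iloc[0]  # median (IQR) summary

    def test_normal_variable_routed_to_ttest(self, rng):
        df = pd.DataFrame({"x": rng.normal(50, 5, 300)})
        group = rng.random(300) < 0.3
        table = compare_descriptives(df, group)
        assert table["test"].iloc[0] == "t-test"
        assert "±" in table["group0"].iloc[0]

    def test_small_group_skipped(self, rng):
        df = pd.DataFrame({"x": rng.normal(size=10)})
        group = np.r_[np.ones(2, bool), np.zeros(8, bool)]
        with pytest.warns(UserWarning):
            table = compare_descriptives(df, group)
        assert len(table) == 0
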