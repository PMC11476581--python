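import math

import numpy as np
import pandas as pd
import pytest
from scipy.optimize import minimize_scalar

from mhcscreen.io import MhcScreenError, RunConfig
from mhcscreen.survival import (
    batch_prognostic_scores,
    fit_cox_univariate,
    kaplan_meier,
    logrank_test,
    prognostic_score_gene,
    truncate_followup,
)
from tests.conftest import make_clinical


def brute_force_cox_beta(time, event, x):
    """Independent oracle: direct O(n^2) evaluation of the Efron partial
    likelihood, maximized by bounded scalar optimization."""
    time = np.asarray(time, float)
    event = np.asarray(event, int)
    x = np.asarray(x, float)

    def neg_ll(beta):
        ll = 0.0
        for t in np.unique(time[event == 1]):
            risk = time >= t
            tied = (time == t) & (event == 1)
            d = tied.sum()
            r_sum = np.exp(beta * x[risk]).sum()
            t_sum = np.exp(beta * x[tied]).sum()
            ll += beta * x[tied].sum()
            for l in range(d):
                ll -= math.log(r_sum - (l / d) * t_sum)
        return -ll

    res = minimize_scalar(neg_ll, bounds=(-10, 10), method="bounded",
                          options={"xatol": 1e-8})
    return res.x


class TestCox:
    def test_matches_brute_force_on_random_data(self):
        rng = np.random.default_rng(5)
        for _ in range(10):
            n = int(rng.integers(20, 60))
            x = rng.normal(size=n)
            t = rng.exponential(np.exp(-0.5 * x))
            c = rng.exponential(2.0, n)
            time = np.minimum(t, c)
            event = (t <= c).astype(int)
            if event.sum() < 3:
                continue
            fit = fit_cox_univariate(time, event, x)
            assert fit.converged
            assert fit.beta == pytest.approx(brute_force_cox_beta(time, event, x), abs=1e-3)

    def test_matches_lifelines_with_ties(self):
        lifelines = pytest.importorskip("lifelines")
        rng = np.random.default_rng(0)
        n = 150
        x = rng.normal(size=n)
        t = np.round(rng.exponential(np.exp(-0.7 * x)), 1)  # heavy ties
        c = rng.exponential(2.0, n)
        time = np.minimum(t, c)
        event = (t <= c).astype(int)
        fit = fit_cox_univariate(time, event, x)
        cph = lifelines.CoxPHFitter().fit(
            pd.DataFrame({"t": time, "e": event, "x": x}), "t", "e")
        assert fit.beta == pytest.approx(float(cph.params_["x"]), abs=1e-5)
        assert fit.se == pytest.approx(float(cph.standard_errors_["x"]), abs=1e-5)

    def test_gradient_small_at_solution(self):
        from mhcscreen.survival import _EfronPartialLikelihood
        rng = np.random.default_rng(2)
        n = 80
        x = rng.normal(size=n)
        t = rng.exponential(np.exp(-0.3 * x))
        event = np.ones(n, dtype=int)
        fit = fit_cox_univariate(t, event, x)
        assert fit.converged
        order = np.argsort(t)
        lik = _EfronPartialLikelihood(t[order], event[order], x[order])
        _, grad, _ = lik.derivatives(fit.beta)
        assert abs(grad) < 1e-6

    def test_separation_flags_non_convergence(self):
        # covariate perfectly orders the event times: monotone likelihood
        time = np.arange(1.0, 21.0)
        event = np.ones(20, dtype=int)
        x = -np.arange(20.0)
        fit = fit_cox_univariate(time, event, x)
        assert not fit.converged
        assert fit.message != ""

    def test_zero_variance_covariate_errors(self):
        with pytest.raises(MhcScreenError):
            fit_cox_univariate(np.arange(1.0, 6.0), np.ones(5, int), np.ones(5))

    def test_no_events_errors(self):
        with pytest.raises(MhcScreenError):
            fit_cox_univariate(np.arange(1.0, 6.0), np.zeros(5, int), np.arange(5.0))


class TestKaplanMeier:
    def test_no_events_survival_stays_one(self):
        km = kaplan_meier(np.array([1.0, 2.0, 3.0]), np.array([0, 0, 0]))
        assert km.survival_at(100.0) == 1.0

    def test_all_events_no_censoring(self):
        km = kaplan_meier(np.array([1.0, 2.0, 3.0]), np.array([1, 1, 1]))
        np.testing.assert_allclose(km.survival, [2 / 3, 1 / 3, 0.0])

    def test_mixed_toy_matches_hand_computation(self):
        # times (1,2,2,3,4,5), events (1,1,0,1,1,0): censored-at-2 stays
        # at risk for t=2; hand product-limit: 5/6, 2/3, 4/9, 2/9
        km = kaplan_meier(np.array([1.0, 2, 2, 3, 4, 5]), np.array([1, 1, 0, 1, 1, 0]))
        np.testing.assert_allclose(km.survival, [5 / 6, 2 / 3, 4 / 9, 2 / 9], atol=1e-12)
        assert km.survival_at(0.5) == 1.0

    def test_survival_non_increasing_in_unit_interval(self):
        rng = np.random.default_rng(8)
        km = kaplan_meier(rng.exponential(1.0, 100), rng.integers(0, 2, 100))
        assert np.all(np.diff(km.survival) <= 1e-15)
        assert np.all((km.survival >= 0) & (km.survival <= 1))


class TestLogrank:
    def test_identical_groups_give_null_statistic(self):
        time = np.array([1.0, 2, 3, 4, 1, 2, 3, 4])
        event = np.array([1, 0, 1, 1, 1, 0, 1, 1])
        group = np.array([0, 0, 0, 0, 1, 1, 1, 1])
        chi2, p = logrank_test(time, event, group)
        assert chi2 == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_small_toy_matches_hand_sums(self):
        # hand-computed O-E = -0.3380952..., V = 1.4571201814058956
        time = np.array([1.0, 2, 3, 4, 1.5, 2.5, 3.5, 4.5])
        event = np.array([1, 1, 0, 1, 1, 1, 1, 0])
        group = np.array([0, 0, 0, 0, 1, 1, 1, 1])
        chi2, p = logrank_test(time, event, group)
        assert chi2 == pytest.approx(0.07844815512223965, abs=1e-12)
        assert p == pytest.approx(0.7794115422103929, abs=1e-10)

    def test_invariant_to_label_swap(self):
        rng = np.random.default_rng(4)
        time = rng.exponential(1.0, 60)
        event = rng.integers(0, 2, 60)
        event[0] = 1
        group = rng.integers(0, 2, 60)
        group[:2] = [0, 1]
        a = logrank_test(time, event, group)
        b = logrank_test(time, event, 1 - group)
        assert a[0] == pytest.approx(b[0], abs=1e-12)

    def test_single_group_errors(self):
        with pytest.raises(MhcScreenError):
            logrank_test(np.array([1.0, 2.0]), np.array([1, 1]), np.array([0, 0]))


class TestTruncation:
    @pytest.mark.parametrize("time,event,horizon,expected", [
        ((8.0,), (1,), 5.0, (5.0, 0)),   # event beyond horizon -> censored at horizon
        ((5.0,), (1,), 5.0, (5.0, 1)),   # event exactly at horizon stays an event
        ((3.0,), (0,), 5.0, (3.0, 0)),   # early censoring untouched
    ])
    def test_stated_rules(self, time, event, horizon, expected):
        t, e = truncate_followup(np.array(time), np.array(event), horizon)
        assert (t[0], e[0]) == expected

    def test_horizon_beyond_max_time_is_identity(self):
        time = np.array([1.0, 4.0, 2.5])
        event = np.array([1, 0, 1])
        t, e = truncate_followup(time, event, 10.0)
        np.testing.assert_array_equal(t, time)
        np.testing.assert_array_equal(e, event)

    def test_never_increases_time_nor_creates_events(self):
        rng = np.random.default_rng(6)
        time = rng.exponential(3.0, 200)
        event = rng.integers(0, 2, 200)
        for horizon in (0.5, 2.0, 5.0, math.inf):
            t, e = truncate_followup(time, event, horizon)
            assert np.all(t <= time)
            assert np.all(e <= event)


def _signal_clinical(rng, x, beta, n_endpoints=4):
    times, events = {}, {}
    for k in range(n_endpoints):
        lam = 0.2 * np.exp(beta * x)
        t = rng.exponential(1.0 / lam)
        c = rng.exponential(10.0, x.size)
        times[f"E{k}"] = np.minimum(t, c)
        events[f"E{k}"] = (t <= c).astype(int)
    return make_clinical(times, events)


class TestPrognosticScore:
    def test_strong_signal_attains_lower_bound(self):
        rng = np.random.default_rng(10)
        n = 500
        x = rng.normal(size=n)
        clinical = _signal_clinical(rng, x, beta=1.0)
        g = pd.Series(x, index=clinical.sample_ids)
        s = prognostic_score_gene(g, clinical, clinical.sample_ids, "BRCA",
                                  endpoints=list(clinical.endpoints),
                                  horizons=[1, 3, 5, 10, math.inf])
        assert s.score == -20
        assert s.risky

    def test_score_equals_sum_of_audit_records(self):
        rng = np.random.default_rng(11)
        n = 200
        x = rng.normal(size=n)
        clinical = _signal_clinical(rng, x, beta=0.3)
        g = pd.Series(x, index=clinical.sample_ids)
        s = prognostic_score_gene(g, clinical, clinical.sample_ids, "BRCA",
                                  endpoints=list(clinical.endpoints),
                                  horizons=[1, 3, 5, 10, math.inf])
        assert s.score == sum(r.contribution for r in s.records)
        assert abs(s.score) <= 20
        assert len(s.records) == 20

    def test_antisymmetric_under_covariate_negation(self):
        rng = np.random.default_rng(12)
        n = 300
        x = rng.normal(size=n)
        clinical = _signal_clinical(rng, x, beta=0.5)
        kwargs = dict(endpoints=list(clinical.endpoints), horizons=[1, 3, 5, 10, math.inf])
        s_pos = prognostic_score_gene(pd.Series(x, index=clinical.sample_ids), clinical,
                                      clinical.sample_ids, "BRCA", **kwargs)
        s_neg = prognostic_score_gene(pd.Series(-x, index=clinical.sample_ids), clinical,
                                      clinical.sample_ids, "BRCA", **kwargs)
        assert s_pos.score == -s_neg.score

    def test_all_fits_skipped_reports_unavailable(self):
        rng = np.random.default_rng(13)
        n = 10  # below the 20-sample floor for every cell
        x = rng.normal(size=n)
        clinical = _signal_clinical(rng, x, beta=0.0, n_endpoints=1)
        s = prognostic_score_gene(pd.Series(x, index=clinical.sample_ids), clinical,
                                  clinical.sample_ids, "BRCA",
                                  endpoints=["E0"], horizons=[5.0])
        assert s.score is None
        assert not s.risky
        assert all(r.skipped for r in s.records)

    def test_batch_risky_count_and_strictness(self, small_cohort, run_config):
        genes = small_cohort.truth.planted_negative[:3] + small_cohort.truth.decoys[:2]
        table = batch_prognostic_scores(small_cohort.expression, small_cohort.clinical,
                                        genes=genes, config=run_config)
        # planted genes are risky in (strictly) more than 3 of 6 cohorts
        for g in small_cohort.truth.planted_negative[:3]:
            assert table.n_cohorts_risky(g) > 3
        # decoys are not broadly risky
        for g in small_cohort.truth.decoys[:2]:
            assert table.n_cohorts_risky(g) <= 3
        df = table.to_frame()
        assert list(df.index) == genes
        audit = table.audit_frame()
        # every score re-derivable from its own audit trail
        for g in genes:
            for c in table.cohorts:
                sub = audit[(audit.gene == g) & (audit.cohort == c)]
                assert table.score(g, c) == sub.contribution.sum()
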