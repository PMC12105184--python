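"""Partial-likelihood engine: closed forms, oracles, variance formulas."""

import numpy as np
import pandas as pd
import pytest

from repwp.balance import StratumWeights
from repwp.cox import (
    FitError,
    ModelSpec,
    fit,
    fit_ag,
    fit_cox_first_event,
    fit_lwyy,
    fit_pwp_gt,
    fit_pwp_robust,
    fit_weighted_pwp,
    neg_log_partial_likelihood,
    score,
)

from conftest import make_history, random_history


def brute_force_neg_loglik(beta, h, weights=None):
    """Direct evaluation of the stratified weighted partial likelihood.

    Loops rows and risk sets literally; Breslow handling of ties; gap scale.
    """
    df = h.table
    ll = 0.0
    for k in sorted(df["k"].unique()):
        g = df[df["k"] == k].reset_index()
        w = np.ones(len(g))
        if weights is not None and k in weights:
            wmap = dict(zip(weights[k].subject_ids, weights[k].weights))
            w = np.array([wmap[i] for i in g["id"]])
        eta = beta * g["treatment"].to_numpy()
        for i in range(len(g)):
            if g.loc[i, "status"] != 1:
                continue
            t = g.loc[i, "stop"]
            at_risk = (g["stop"].to_numpy() >= t) & (g["start"].to_numpy() < t)
            denom = np.sum(w[at_risk] * np.exp(eta[at_risk]))
            ll += w[i] * (eta[i] - np.log(denom))
    return -ll


def _grid_min(f, lo=-3.0, hi=3.0):
    """Exhaustive grid minimizer refined to a 1e-4 mesh."""
    coarse = np.arange(lo, hi, 0.01)
    c = coarse[int(np.argmin([f(b) for b in coarse]))]
    fine = np.arange(c - 0.02, c + 0.02, 1e-4)
    return fine[int(np.argmin([f(b) for b in fine]))]


class TestLikelihood:
    def test_null_value_is_sum_log_risk_set_sizes(self):
        # at beta=0, each event contributes log(size of its risk set)
        rows = [
            (1, 1, 0, 1.0, 1, 1, 0.0),
            (2, 1, 0, 2.0, 1, 0, 0.0),
            (3, 1, 0, 3.0, 0, 0, 0.0),
        ]
        h = make_history(rows)
        spec = ModelSpec(risk_interval="gap")
        val = neg_log_partial_likelihood(0.0, h, spec)
        assert val == pytest.approx(np.log(3) + np.log(2))

    def test_three_subject_hand_evaluation(self):
        # times 1,2,3; statuses 1,1,0; arms 1,0,0 at beta=0.5
        rows = [
            (1, 1, 0, 1.0, 1, 1, 0.0),
            (2, 1, 0, 2.0, 1, 0, 0.0),
            (3, 1, 0, 3.0, 0, 0, 0.0),
        ]
        h = make_history(rows)
        b = 0.5
        hand = -(b - np.log(np.exp(b) + 2)) - (0 - np.log(2))
        got = neg_log_partial_likelihood(b, h, ModelSpec(risk_interval="gap"))
        assert got == pytest.approx(hand, rel=1e-12)

    def test_matches_brute_force_on_random_histories(self, rng):
        for _ in range(10):
            h = random_history(rng, n_subjects=8)
            b = float(rng.normal(scale=0.7))
            spec = ModelSpec(risk_interval="gap", stratify_by_event_number=True)
            assert neg_log_partial_likelihood(b, h, spec) == pytest.approx(
                brute_force_neg_loglik(b, h), rel=1e-10
            )

    def test_no_events_is_an_error(self):
        h = make_history([(1, 1, 0, 1.0, 0, 1, 0.0), (2, 1, 0, 2.0, 0, 0, 0.0)])
        with pytest.raises(FitError):
            neg_log_partial_likelihood(0.0, h, ModelSpec())


class TestScore:
    def test_null_score_is_event_minus_risk_set_mean(self):
        rows = [
            (1, 1, 0, 1.0, 1, 1, 0.0),
            (2, 1, 0, 2.0, 1, 0, 0.0),
            (3, 1, 0, 3.0, 0, 0, 0.0),
        ]
        h = make_history(rows)
        # event 1: risk set {1,2,3}, mean A = 1/3; event 2: risk set {2,3},
        # mean A = 0 (subject 1 has left)
        expected = (1 - 1 / 3) + (0 - 0)
        got = score(0.0, h, ModelSpec(risk_interval="gap"))
        assert got[0] == pytest.approx(expected)

    def test_score_is_numerical_gradient(self, rng):
        spec = ModelSpec(risk_interval="gap", stratify_by_event_number=True)
        for _ in range(10):
            h = random_history(rng, n_subjects=10)
            b = float(rng.normal(scale=0.5))
            eps = 1e-6
            num = -(
                neg_log_partial_likelihood(b + eps, h, spec)
                - neg_log_partial_likelihood(b - eps, h, spec)
            ) / (2 * eps)
            assert score(b, h, spec)[0] == pytest.approx(num, rel=1e-5, abs=1e-6)

    def test_score_vanishes_at_fit(self, rng):
        h = random_history(rng, n_subjects=30)
        spec = ModelSpec(risk_interval="gap", stratify_by_event_number=True)
        fr = fit(h, spec)
        assert abs(score(fr.coef, h, spec)[0]) < 1e-8


class TestFit:
    def test_grid_search_oracle_small_fixture(self, rng):
        spec = ModelSpec(risk_interval="gap", stratify_by_event_number=True)
        for seed in range(3):
            h = random_history(np.random.default_rng(seed + 100), n_subjects=8)
            if h.n_events < 2 or h.table.groupby("treatment").size().min() < 2:
                continue
            try:
                fr = fit(h, spec)
            except FitError:
                continue
            if abs(fr.coef) > 2.5:  # grid window is [-3, 3]
                continue
            best = _grid_min(lambda b: brute_force_neg_loglik(b, h))
            assert fr.coef == pytest.approx(best, abs=1e-3)

    def test_weighted_grid_search_oracle(self):
        rows = [
            (1, 1, 0, 1.0, 1, 1, 0.0), (1, 2, 0, 0.5, 1, 1, 0.0),
            (2, 1, 0, 2.0, 1, 0, 0.0), (2, 2, 0, 1.5, 0, 0, 0.0),
            (3, 1, 0, 3.0, 1, 1, 0.0), (3, 2, 0, 2.5, 0, 1, 0.0),
            (4, 1, 0, 4.0, 0, 0, 0.0),
            (5, 1, 0, 5.0, 0, 0, 0.0),
        ]
        h = make_history(rows)
        weights = {
            1: StratumWeights(1, (1, 2, 3, 4, 5), np.ones(5), True, 0, 0),
            2: StratumWeights(2, (1, 2, 3), np.array([0.8, 1.4, 0.8]), True, 0, 0),
        }
        spec = ModelSpec(
            risk_interval="gap", stratify_by_event_number=True, weights=weights
        )
        fr = fit(h, spec)
        best = _grid_min(lambda b: brute_force_neg_loglik(b, h, weights))
        assert fr.coef == pytest.approx(best, abs=1e-3)

    def test_weight_rescaling_leaves_estimate_unchanged(self):
        rows = [
            (1, 1, 0, 1.0, 1, 1, 0.0), (1, 2, 0, 0.5, 1, 1, 0.0),
            (2, 1, 0, 2.0, 1, 0, 0.0), (2, 2, 0, 1.5, 0, 0, 0.0),
            (3, 1, 0, 3.0, 1, 1, 0.0), (3, 2, 0, 2.5, 0, 1, 0.0),
            (4, 1, 0, 4.0, 0, 0, 0.0),
        ]
        h = make_history(rows)

        def wspec(c):
            # every stratum rescaled by the same positive constant: the
            # score equation is scale-equivariant, so the root is unchanged
            return ModelSpec(
                risk_interval="gap",
                stratify_by_event_number=True,
                weights={
                    1: StratumWeights(1, (1, 2, 3, 4), c * np.ones(4), True, 0, 0),
                    2: StratumWeights(
                        2, (1, 2, 3), c * np.array([0.7, 1.2, 1.1]), True, 0, 0
                    ),
                },
            )

        assert fit(h, wspec(1.0)).coef == pytest.approx(
            fit(h, wspec(3.5)).coef, abs=1e-9
        )

    def test_separation_detected(self):
        # all events in one arm, none in the other, strongly separated times
        rows = [(i, 1, 0, 0.1 + 0.1 * i, 1, 1, 0.0) for i in range(5)] + [
            (10 + i, 1, 0, 50.0 + i, 0, 0, 0.0) for i in range(5)
        ]
        h = make_history(rows)
        with pytest.raises(FitError):
            fit(h, ModelSpec(risk_interval="gap"))


@pytest.fixture(scope="module")
def trial():
    from repwp.simulate import make_scenario, simulate_trial

    return simulate_trial(make_scenario(1, n=120, seed=77))


class TestAgainstLifelines:
    """Independent implementation check on continuous (tie-free) data,
    where lifelines' Efron tie handling coincides with Breslow."""

    def test_cox_first_event_matches_lifelines(self, trial):
        lifelines = pytest.importorskip("lifelines")
        from repwp.data import first_event_subset

        sub = first_event_subset(trial.history).table
        cph = lifelines.CoxPHFitter()
        cph.fit(
            sub[["stop", "status", "treatment"]],
            duration_col="stop",
            event_col="status",
        )
        fr = fit_cox_first_event(trial.history)
        assert fr.coef == pytest.approx(cph.params_["treatment"], abs=1e-5)
        assert fr.naive_se == pytest.approx(cph.standard_errors_["treatment"], abs=1e-5)

    def test_ag_matches_lifelines_counting_process(self, trial):
        lifelines = pytest.importorskip("lifelines")
        from repwp.data import to_counting_process

        df = to_counting_process(trial.history).table[
            ["id", "start", "stop", "status", "treatment"]
        ]
        ctv = lifelines.CoxTimeVaryingFitter()
        ctv.fit(df, id_col="id", start_col="start", stop_col="stop", event_col="status")
        fr = fit_ag(trial.history)
        assert fr.coef == pytest.approx(ctv.params_["treatment"], abs=1e-5)


class TestVariance:
    def test_sandwich_formula_three_subject_hand_case(self):
        # single stratum, one row per subject, unit weights; events at
        # t=1 (control) and t=2 (treated) so the optimum is interior
        rows = [
            (1, 1, 0, 1.0, 1, 0, 0.0),
            (2, 1, 0, 2.0, 1, 1, 0.0),
            (3, 1, 0, 3.0, 0, 0, 0.0),
        ]
        h = make_history(rows)
        fr = fit(h, ModelSpec(risk_interval="gap", variance="robust_cluster"))
        e = np.exp(fr.coef)
        # risk sets: t=1 {1,2,3} with S0 = 2+e; t=2 {2,3} with S0 = 1+e
        s1, s2 = 2 + e, 1 + e
        m1, m2 = e / s1, e / s2
        info = (m1 - m1**2) + (m2 - m2**2)
        u1 = (0 - m1) - 1 * (0 - m1) / s1
        u2 = (1 - m2) - e * ((1 - m1) / s1 + (1 - m2) / s2)
        u3 = -1 * ((0 - m1) / s1 + (0 - m2) / s2)
        expected_rse = np.sqrt((u1**2 + u2**2 + u3**2) / info**2)
        assert fr.robust_se == pytest.approx(expected_rse, rel=1e-8)
        assert fr.naive_se == pytest.approx(1 / np.sqrt(info), rel=1e-8)

    def test_robust_se_positive_and_ci_ordering(self, rng):
        h = random_history(rng, n_subjects=40)
        fr = fit_pwp_robust(h)
        lo, hi = fr.ci95
        assert fr.robust_se > 0 and lo < fr.hr < hi


class TestPresets:
    def test_ag_and_lwyy_identical_point_estimates(self, bladder):
        a, l = fit_ag(bladder), fit_lwyy(bladder)
        assert a.coef == pytest.approx(l.coef, abs=1e-12)
        assert a.ci95 != l.ci95

    def test_unit_weight_weighted_pwp_equals_pwp_robust(self, rng):
        from repwp.data import to_gap_time, truncate_strata
        from repwp.balance import eligible_strata

        h = random_history(rng, n_subjects=60, max_events=3)
        wf = fit_weighted_pwp(h, weight_method="none")
        # reference: PWP-robust restricted to the same eligible strata
        hh = truncate_strata(to_gap_time(h), eligible_strata(h))
        pr = fit_pwp_robust(hh)
        assert wf.coef == pytest.approx(pr.coef, abs=1e-12)
        assert wf.robust_se == pytest.approx(pr.robust_se, rel=1e-12)

    def test_adjusted_fit_reports_treatment_row(self, bladder):
        fr = fit_pwp_gt(bladder, adjust=["number", "size"])
        assert fr.term_names[0] == "treatment"
        assert len(fr.coef_all) == 3
        assert fr.coef == pytest.approx(fr.coef_all[0])

    def test_adjusted_fit_vs_2d_grid_oracle(self):
        rng = np.random.default_rng(9)
        rows = []
        for i in range(10):
            rows.append(
                (i, 1, 0.0, float(rng.exponential(2) + 0.1),
                 int(rng.integers(0, 2)), i % 2, float(rng.normal()))
            )
        h = make_history(rows)
        if h.n_events < 3:
            pytest.skip("degenerate draw")
        fr = fit(h, ModelSpec(risk_interval="gap", adjust_covariates=["x1"]))

        def nll2(b, g):
            df = h.table
            eta = b * df["treatment"].to_numpy() + g * df["x1"].to_numpy()
            ll = 0.0
            for i in range(len(df)):
                if df.loc[i, "status"] != 1:
                    continue
                t = df.loc[i, "stop"]
                at = df["stop"].to_numpy() >= t
                ll += eta[i] - np.log(np.sum(np.exp(eta[at])))
            return -ll

        bg = np.arange(-3, 3, 0.05)
        best = min(((nll2(b, g), b, g) for b in bg for g in bg))
        b0, g0 = best[1], best[2]
        fine_b = np.arange(b0 - 0.1, b0 + 0.1, 0.002)
        fine_g = np.arange(g0 - 0.1, g0 + 0.1, 0.002)
        best = min(((nll2(b, g), b, g) for b in fine_b for g in fine_g))
        assert fr.coef == pytest.approx(best[1], abs=0.003)
        assert fr.coef_all[1] == pytest.approx(best[2], abs=0.003)

    def test_uncorrelated_covariate_leaves_estimate_nearly_unchanged(self, rng):
        h = random_history(rng, n_subjects=50)
        df = h.table.copy()
        # covariate orthogonal to treatment by construction: alternate signs
        base = fit_pwp_gt(h).coef
        adj = fit_pwp_gt(h, adjust=["x1"])
        # x1 was generated independently of everything: estimates stay close
        assert adj.coef == pytest.approx(base, abs=0.3)
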