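"""Score engine: weights, raw scores, separability identity, Lin–Wei shifts."""

import numpy as np
import pandas as pd
import pytest

from survdelta import (
    SimulationConfig,
    event_restricted,
    fit_null,
    score_table,
    separability_form,
    simulate_cohort,
    weights,
)
from survdelta.exceptions import DegenerateCohortError
from survdelta.nullfit import StratumNullEstimates, baseline_cumhaz
from tests.conftest import random_cohort


def _estimates(surv_left, surv_right, theta_hat):
    k = len(surv_left)
    est = StratumNullEstimates(
        stratum=0,
        event_times=np.arange(1.0, k + 1.0),
        n_events_at=np.ones(k, dtype=int),
        n_at_risk=np.arange(k, 0, -1),
        surv_left=np.asarray(surv_left, dtype=float),
        surv_right=np.asarray(surv_right, dtype=float),
        surv_plateau=float(surv_right[-1]),
    )
    est.theta_hat = theta_hat
    baseline_cumhaz(est)
    return est


def _two_subject_cohort():
    """z = (1, 0); subject 1 fails first, subject 2 fails later."""
    return pd.DataFrame(
        {
            "entry_age": [0.0, 0.0],
            "followup_age": [1.0, 2.0],
            "event": [1, 1],
            "marker": [1.0, 0.0],
            "stratum": [0, 0],
        }
    )


class TestWeights:
    def test_w2_is_one_at_the_first_event(self, null_cohort):
        estimates = fit_null(null_cohort)
        est = estimates[0]
        _, w2 = weights(est, float(est.event_times[0]))
        assert w2 == pytest.approx(1.0, abs=1e-12)

    def test_w1_direct_value(self):
        # S(a-) = 1, exp(-theta) = 0.7: w1 = 0.7 * (-log 0.7)
        theta = -np.log(0.7)
        est = _estimates([1.0, 0.9], [0.9, 0.7], theta)
        w1, _ = weights(est, 1.0)
        assert w1 == pytest.approx(0.7 * theta, abs=1e-12)
        assert w1 == pytest.approx(0.2497, abs=5e-4)

    def test_w2_goes_negative_at_high_cumulative_hazard(self):
        # exp(-theta)=0.7, Lambda0=2, S=0.7406: w2 ~ -0.890
        theta = -np.log(0.7)
        surv = 0.7 + 0.3 * np.exp(-2.0)  # survival consistent with Lambda0 = 2
        est = _estimates([1.0, surv], [surv, 0.7], theta)
        _, w2 = weights(est, 2.0)
        expected = (0.7 * (1 - np.exp(-2.0) - 2.0) + np.exp(-2.0)) / surv
        assert w2 == pytest.approx(expected, abs=1e-12)
        assert w2 == pytest.approx(-0.890, abs=2e-3)

    def test_between_event_ages_uses_right_continuous_values(self):
        est = _estimates([1.0, 0.9], [0.9, 0.7], -np.log(0.7))
        w_at_15 = weights(est, 1.5)
        w_left_of_2 = weights(est, 2.0)
        assert w_at_15 == pytest.approx(w_left_of_2, abs=1e-12)


class TestRawScores:
    def test_two_subject_hand_value(self):
        cohort = _two_subject_cohort()
        table = score_table(cohort, fit_null(cohort))
        # at the first event S(a-) = 1, Lambda0 = 0 so w2 = 1 exactly;
        # risk set mean of z is 0.5 -> U2 = 1 * (1 - 0.5) = 0.5
        assert table.loc[0, "score_u2"] == pytest.approx(0.5, abs=1e-12)

    def test_constant_marker_kills_every_score(self, null_cohort):
        cohort = null_cohort.copy()
        cohort["marker"] = 3.14
        table = score_table(cohort, fit_null(cohort))
        assert np.allclose(table[["score_u1", "score_u2"]], 0.0)

    def test_single_subject_stratum_scores_zero(self):
        cohort = pd.DataFrame(
            {
                "entry_age": [0.0],
                "followup_age": [1.0],
                "event": [1],
                "marker": [2.0],
                "stratum": [0],
            }
        )
        table = score_table(cohort, fit_null(cohort))
        assert table["score_u1"].iloc[0] == 0.0
        assert table["score_u2"].iloc[0] == 0.0

    def test_censored_rows_have_zero_raw_scores(self, null_cohort):
        table = score_table(null_cohort, fit_null(null_cohort))
        censored = table["event"] == 0
        assert np.allclose(table.loc[censored, ["score_u1", "score_u2"]], 0.0)
        # their shifted scores are generally non-zero
        assert not np.allclose(table.loc[censored, "shifted_w1"], 0.0)


class TestSeparabilityIdentity:
    def test_two_subject_hand_value(self):
        cohort = _two_subject_cohort()
        sep = separability_form(cohort, fit_null(cohort))
        assert sep.loc[0, "score_u2"] == pytest.approx(0.5, abs=1e-12)

    def test_identity_on_random_cohorts(self, rng):
        for _ in range(100):
            cohort = random_cohort(rng, n=50, n_strata=2)
            estimates = fit_null(cohort)
            table = score_table(cohort, estimates)
            sep = separability_form(cohort, estimates)
            diff = np.abs(
                table[["score_u1", "score_u2"]].to_numpy()
                - sep[["score_u1", "score_u2"]].to_numpy()
            )
            assert diff.max() < 1e-10

    def test_singleton_risk_set_returns_zero_in_both_forms(self):
        cohort = pd.DataFrame(
            {
                "entry_age": [0.0],
                "followup_age": [1.0],
                "event": [1],
                "marker": [5.0],
                "stratum": [0],
            }
        )
        estimates = fit_null(cohort)
        assert separability_form(cohort, estimates)["score_u2"].iloc[0] == 0.0
        assert score_table(cohort, estimates)["score_u2"].iloc[0] == 0.0


class TestShiftedScores:
    def test_single_subject_shifted_score_vanishes(self):
        cohort = pd.DataFrame(
            {
                "entry_age": [0.0],
                "followup_age": [1.0],
                "event": [1],
                "marker": [2.0],
                "stratum": [0],
            }
        )
        table = score_table(cohort, fit_null(cohort))
        assert table["shifted_w1"].iloc[0] == 0.0
        assert table["shifted_w2"].iloc[0] == 0.0

    def test_censoring_before_first_event_leaves_zero_shift(self):
        cohort = pd.DataFrame(
            {
                "entry_age": [0.0] * 3,
                "followup_age": [0.5, 1.0, 2.0],
                "event": [0, 1, 1],
                "marker": [1.0, 0.0, -1.0],
                "stratum": [0] * 3,
            }
        )
        table = score_table(cohort, fit_null(cohort))
        assert table.loc[0, "shift_u1"] == 0.0
        assert table.loc[0, "shifted_w1"] == 0.0

    def test_unit_weights_reduce_to_cox_score_residuals(self, rng):
        # forcing theta -> inf makes w2 = exp(-Lambda)/S = 1 at every event age,
        # so shifted_w2 must equal the classical Cox score residual at beta = 0
        for _ in range(20):
            cohort = random_cohort(rng, n=40)
            estimates = fit_null(cohort)
            for est in estimates.values():
                est.theta_hat = np.inf
                baseline_cumhaz(est)
            table = score_table(cohort, estimates)
            ref = _cox_score_residuals_at_zero(cohort)
            assert np.max(np.abs(table["shifted_w2"].to_numpy() - ref)) < 1e-8

    def test_translation_invariance_and_scaling(self, null_cohort):
        base = score_table(null_cohort, fit_null(null_cohort))
        shifted = null_cohort.assign(marker=null_cohort["marker"] + 100.0)
        scaled = null_cohort.assign(marker=null_cohort["marker"] * -2.5)
        cols = ["score_u1", "score_u2", "shifted_w1", "shifted_w2"]
        t_shift = score_table(shifted, fit_null(shifted))
        t_scale = score_table(scaled, fit_null(scaled))
        assert np.allclose(t_shift[cols], base[cols], atol=1e-10)
        assert np.allclose(t_scale[cols], -2.5 * base[cols], atol=1e-10)

    def test_null_shifted_scores_center_on_zero_across_replications(self):
        # E[W*] = 0 under no marker effect: replication means within 3 MC SEs
        means1, means2 = [], []
        for rep in range(200):
            cohort = simulate_cohort(
                SimulationConfig(tail_defect=0.5, n_subjects=200, seed=1000 + rep)
            )
            wstar = event_restricted(score_table(cohort, fit_null(cohort)))
            means1.append(wstar["shifted_w1"].mean())
            means2.append(wstar["shifted_w2"].mean())
        for means in (means1, means2):
            m = np.mean(means)
            se = np.std(means, ddof=1) / np.sqrt(len(means))
            assert abs(m) < 3 * se


class TestEventRestricted:
    def test_counts_preserved(self, null_cohort):
        table = score_table(null_cohort, fit_null(null_cohort))
        wstar = event_restricted(table)
        assert len(wstar) == int(null_cohort["event"].sum())

    def test_two_events_is_degenerate(self):
        cohort = _two_subject_cohort()
        table = score_table(cohort, fit_null(cohort))
        with pytest.raises(DegenerateCohortError):
            event_restricted(table)


def _cox_score_residuals_at_zero(cohort: pd.DataFrame) -> np.ndarray:
    """Literal loop transcription of the Cox score residual at beta = 0."""
    x = cohort["followup_age"].to_numpy(dtype=float)
    d = cohort["event"].to_numpy().astype(bool)
    z = cohort["marker"].to_numpy(dtype=float)
    n = x.size
    res = np.zeros(n)
    event_ages = np.unique(x[d])
    for i in range(n):
        if d[i]:
            risk = x >= x[i]
            res[i] = z[i] - z[risk].mean()
        for a in event_ages:
            if x[i] >= a:
                risk = x >= a
                d_l = int(((x == a) & d).sum())
                res[i] -= (d_l / risk.sum()) * (z[i] - z[risk].mean())
    return res
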