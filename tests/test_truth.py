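"""Analytic truth engine: intercept solving, population moments, true effects."""

import math

import numpy as np
import pytest
from scipy.special import expit

from medlogit import (
    BINARY,
    CONTINUOUS,
    CRUDE,
    FULL_STD,
    POTENTIAL_OUTCOMES,
    STD_LOGISTIC,
    Y_STD,
    Condition,
    paper_conditions,
    true_effects,
    truth_table,
)
from medlogit.exceptions import InputError
from medlogit.truth import mediator_intercept, outcome_intercept, true_moments


def mc_prevalence(i2, a, n=10_000_000, seed=1):
    x = np.random.default_rng(seed).standard_normal(n)
    return expit(i2 + a * x).mean()


class TestInterceptSolver:
    def test_symmetric_target_gives_zero(self):
        cond = Condition(BINARY, y_prevalence=0.5, m_prevalence=0.5)
        assert mediator_intercept(cond) == pytest.approx(0.0, abs=1e-10)
        # continuous mediator: the outcome linear predictor is symmetric too
        cont = Condition(CONTINUOUS, y_prevalence=0.5)
        assert outcome_intercept(cont, 0.0) == pytest.approx(0.0, abs=1e-10)

    def test_binary_mediator_shifts_outcome_intercept_by_half_b(self):
        # M is 0/1, so at prevalences 0.5/0.5 the symmetry X->-X, M->1-M
        # fixes the outcome intercept at exactly -b/2
        cond = Condition(BINARY, y_prevalence=0.5, m_prevalence=0.5)
        assert outcome_intercept(cond, 0.0) == pytest.approx(-0.3, abs=1e-9)

    def test_prevalence_03_against_monte_carlo(self):
        cond = Condition(BINARY, y_prevalence=0.5, m_prevalence=0.3)
        i2 = mediator_intercept(cond)
        assert i2 == pytest.approx(-0.9, abs=0.05)
        # 10^7-draw Monte-Carlo oracle of the marginal prevalence
        assert mc_prevalence(i2, 0.6) == pytest.approx(0.3, abs=5e-4)

    def test_monotone_in_target(self):
        intercepts = [
            mediator_intercept(Condition(BINARY, y_prevalence=0.5, m_prevalence=p))
            for p in (0.1, 0.3, 0.5, 0.7, 0.9)
        ]
        assert intercepts == sorted(intercepts)

    def test_outcome_intercept_hits_prevalence_continuous(self):
        # Monte-Carlo check of the marginal Y prevalence under the full model
        cond = Condition(CONTINUOUS, y_prevalence=0.1)
        truth = true_effects(cond)
        rng = np.random.default_rng(5)
        x = rng.standard_normal(2_000_000)
        m = 0.6 * x + rng.standard_normal(2_000_000)
        prev = expit(truth.i3_true + 0.6 * x + 0.6 * m).mean()
        assert prev == pytest.approx(0.1, abs=1e-3)

    def test_invalid_target_rejected(self):
        with pytest.raises(InputError):
            Condition(BINARY, y_prevalence=0.5, m_prevalence=1.5)


class TestTrueMoments:
    def test_continuous_closed_form(self):
        cond = Condition(CONTINUOUS, y_prevalence=0.5)
        var_m, cov = true_moments(cond, 0.0)
        assert var_m == pytest.approx(1.36)
        assert cov == pytest.approx(0.6)

    def test_binary_prevalence_half(self):
        cond = Condition(BINARY, y_prevalence=0.5, m_prevalence=0.5)
        var_m, cov = true_moments(cond, 0.0)
        assert var_m == pytest.approx(0.25, abs=1e-10)
        # Stein-identity form: COV = a * E[p(1-p)]
        z = np.random.default_rng(2).standard_normal(10_000_000)
        p = expit(0.6 * z)
        stein = 0.6 * np.mean(p * (1 - p))
        assert cov == pytest.approx(0.1385, abs=1e-3)
        assert cov == pytest.approx(stein, abs=4 * np.std(z * p) / math.sqrt(z.size))

    def test_binary_moments_match_monte_carlo(self):
        cond = Condition(BINARY, y_prevalence=0.5, m_prevalence=0.3)
        i2 = mediator_intercept(cond)
        var_m, cov = true_moments(cond, i2)
        rng = np.random.default_rng(3)
        x = rng.standard_normal(10_000_000)
        m = (rng.random(x.size) < expit(i2 + 0.6 * x)).astype(float)
        se_cov = np.std(x * m) / math.sqrt(x.size)
        assert cov == pytest.approx(np.mean(x * m), abs=4 * se_cov)
        assert var_m == pytest.approx(np.var(m), abs=1e-3)


class TestTrueEffects:
    def test_crude_truth_in_all_conditions(self):
        table = truth_table()
        crude = table[table.method == CRUDE]
        assert len(crude) == 12
        assert np.allclose(crude.ie_true, 0.360)
        assert np.allclose(crude.pm_true, 0.375)

    def test_y_standardized_truths(self):
        cont = true_effects(Condition(CONTINUOUS, y_prevalence=0.5))
        assert cont.ie_true[Y_STD] == pytest.approx(0.168, abs=5e-4)
        bin5 = true_effects(Condition(BINARY, y_prevalence=0.5, m_prevalence=0.5))
        assert bin5.ie_true[Y_STD] == pytest.approx(0.096, abs=5e-4)

    def test_full_standardized_binary_truths(self):
        bin5 = true_effects(Condition(BINARY, y_prevalence=0.5, m_prevalence=0.5))
        bin3 = true_effects(Condition(BINARY, y_prevalence=0.5, m_prevalence=0.3))
        assert bin5.ie_true[FULL_STD] == pytest.approx(0.048, abs=5e-4)
        assert bin3.ie_true[FULL_STD] == pytest.approx(0.044, abs=5e-4)

    def test_potential_outcomes_truths(self):
        cont = true_effects(Condition(CONTINUOUS, y_prevalence=0.5))
        assert cont.ie_true[POTENTIAL_OUTCOMES] == pytest.approx(0.360)
        assert cont.ie_true[STD_LOGISTIC] == pytest.approx(0.360)
        for prev, ie_expected, tol in [(0.5, 0.081, 5e-4), (0.3, 0.087, 5e-4), (0.1, 0.047, 5e-3)]:
            row = true_effects(Condition(BINARY, y_prevalence=0.5, m_prevalence=prev))
            assert row.ie_true[POTENTIAL_OUTCOMES] == pytest.approx(ie_expected, abs=tol), prev

    def test_potential_outcomes_proportions(self):
        # pm = ie/(ie + 0.6) with ie the natural-effect log-OR
        for prev, pm_expected, tol in [(0.5, 0.119, 1e-3), (0.3, 0.127, 1.5e-3), (0.1, 0.073, 2e-3)]:
            row = true_effects(Condition(BINARY, y_prevalence=0.5, m_prevalence=prev))
            ie = row.ie_true[POTENTIAL_OUTCOMES]
            assert row.pm_true[POTENTIAL_OUTCOMES] == pytest.approx(ie / (ie + 0.6), abs=1e-12)
            assert row.pm_true[POTENTIAL_OUTCOMES] == pytest.approx(pm_expected, abs=tol), prev

    def test_truth_invariant_to_outcome_prevalence(self):
        # standardization uses mediator-side moments only, so the true ie per
        # method depends on the mediator prevalence, not the outcome's
        rows = [
            true_effects(Condition(BINARY, y_prevalence=p, m_prevalence=0.3))
            for p in (0.1, 0.3, 0.5)
        ]
        for method in (CRUDE, Y_STD, FULL_STD, POTENTIAL_OUTCOMES):
            values = [r.ie_true[method] for r in rows]
            assert max(values) - min(values) < 1e-12, method

    def test_grid_has_twelve_conditions(self):
        conds = paper_conditions()
        assert len(conds) == 12
        assert sum(c.mediator_type == CONTINUOUS for c in conds) == 3
        assert len({c.label for c in conds}) == 12
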