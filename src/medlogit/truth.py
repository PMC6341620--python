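"""Analytic true effect values for simulated mediation scenarios.

A :class:`Condition` describes one generating model: a standard-normal
exposure, a continuous (linear-normal) or binary (Bernoulli-logit) mediator,
and a Bernoulli-logit outcome, with target marginal prevalences for the
binary variables.  This module derives, without simulation,

* the generating intercepts that hit the target prevalences (Gauss-Hermite
  quadrature + root finding on the marginal-prevalence equation),
* the population moments VAR(M) and COV(X,M),
* the true value of every estimator family: the crude product ``a*b``, the
  y- and full-standardized products obtained by applying the standardization
  formulas to the true coefficients and true moments, the standardized
  logistic solution, and the potential-outcomes natural indirect effect,
* the true proportions mediated.

The true proportion mediated for the regression-based rows (crude and all
standardizations) is the structural ``ab/(ab+c')``; standardized estimators
are scored against their own rescaled indirect-effect truth but against the
common structural proportion, which is what makes the bias of standardized
proportion-mediated estimators informative.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit

from . import standardization as std
from .data import BINARY, CONTINUOUS
from .effects import POTENTIAL_OUTCOMES, po_binary_log_or
from .exceptions import InputError

#: Gauss-Hermite rule used for all expectations over the normal exposure.
_GH_NODES = 96
_t, _w = np.polynomial.hermite.hermgauss(_GH_NODES)
_Z = np.sqrt(2.0) * _t          # standard-normal abscissae
_W = _w / np.sqrt(np.pi)        # weights summing to 1


@dataclass(frozen=True)
class Condition:
    """One generating scenario for the simulation study.

    Defaults are the study conditions: all structural paths 0.6
    (medium-to-large), unit-variance standard-normal exposure, unit residual
    SD for the continuous mediator, 500 replicates of n=1000.
    """

    mediator_type: str
    y_prevalence: float
    m_prevalence: float | None = None
    a: float = 0.6
    b: float = 0.6
    c_prime: float = 0.6
    var_x: float = 1.0
    m_residual_sd: float = 1.0
    n: int = 1000
    reps: int = 500

    def __post_init__(self):
        if self.mediator_type not in (CONTINUOUS, BINARY):
            raise InputError(f"unknown mediator_type {self.mediator_type!r}")
        if not 0.0 < self.y_prevalence < 1.0:
            raise InputError(f"y_prevalence must be in (0,1), got {self.y_prevalence}")
        if self.mediator_type == BINARY:
            if self.m_prevalence is None or not 0.0 < self.m_prevalence < 1.0:
                raise InputError(
                    f"binary mediator needs m_prevalence in (0,1), got {self.m_prevalence}"
                )
        elif self.m_prevalence is not None:
            raise InputError("m_prevalence is only meaningful for a binary mediator")
        if self.var_x <= 0:
            raise InputError(f"var_x must be positive, got {self.var_x}")

    @property
    def label(self) -> str:
        if self.mediator_type == BINARY:
            return f"binM_m{self.m_prevalence:g}_y{self.y_prevalence:g}"
        return f"contM_y{self.y_prevalence:g}"


@dataclass(frozen=True)
class TruthRow:
    """A condition's derived intercepts, moments and per-method true values."""

    condition: Condition
    i2_true: float
    i3_true: float
    var_m_true: float
    cov_xm_true: float
    ie_true: dict[str, float] = field(repr=False)
    pm_true: dict[str, float] = field(repr=False)


def paper_conditions(n: int = 1000, reps: int = 500) -> list[Condition]:
    """The 12-condition grid: 3 continuous-M and 9 binary-M scenarios."""
    prevalences = (0.1, 0.3, 0.5)
    conds = [Condition(CONTINUOUS, y_prevalence=p, n=n, reps=reps) for p in prevalences]
    conds += [
        Condition(BINARY, y_prevalence=py, m_prevalence=pm, n=n, reps=reps)
        for pm in prevalences
        for py in prevalences
    ]
    return conds


def condition_by_label(label: str, n: int = 1000, reps: int = 500) -> Condition:
    for cond in paper_conditions(n=n, reps=reps):
        if cond.label == label:
            return cond
    known = [c.label for c in paper_conditions()]
    raise InputError(f"unknown condition {label!r}; known labels: {known}")


def _gh_expect(fn) -> float:
    """E[fn(Z)] for Z ~ N(0,1) by Gauss-Hermite quadrature."""
    return float(np.sum(_W * fn(_Z)))


def solve_intercept(target_prev: float, marginal_prev, lo: float = -40.0, hi: float = 40.0) -> float:
    """Intercept ``i`` with ``marginal_prev(i) == target_prev`` to ~1e-12.

    ``marginal_prev`` maps an intercept to the implied marginal probability;
    it must be continuous and increasing (expit is monotone in its shift).
    """
    if not 0.0 < target_prev < 1.0:
        raise InputError(f"target prevalence must be in (0,1), got {target_prev}")
    return float(brentq(lambda i: marginal_prev(i) - target_prev, lo, hi, xtol=1e-12))


def mediator_intercept(cond: Condition) -> float:
    """Generating intercept of the mediator equation.

    Zero for a continuous mediator (mean-zero mediator); for a binary
    mediator the root of E[expit(i + a*X)] = target prevalence.
    """
    if cond.mediator_type == CONTINUOUS:
        return 0.0
    sd_x = np.sqrt(cond.var_x)

    def marginal(i):
        return _gh_expect(lambda z: expit(i + cond.a * sd_x * z))

    return solve_intercept(cond.m_prevalence, marginal)


def outcome_intercept(cond: Condition, i2: float) -> float:
    """Generating intercept of the outcome equation, hitting the Y prevalence.

    For a continuous mediator the linear predictor c'X + bM is normal with
    variance (c'+ab)^2 VAR(X) + b^2 sd_eps^2, so a single quadrature over
    that normal suffices; for a binary mediator the expectation sums over
    M | X inside a quadrature over X.
    """
    sd_x = np.sqrt(cond.var_x)
    if cond.mediator_type == CONTINUOUS:
        eta_sd = np.sqrt(
            (cond.c_prime + cond.a * cond.b) ** 2 * cond.var_x
            + (cond.b * cond.m_residual_sd) ** 2
        )

        def marginal(i):
            return _gh_expect(lambda z: expit(i + eta_sd * z))

    else:

        def marginal(i):
            x = sd_x * _Z
            p_m1 = expit(i2 + cond.a * x)
            py = (1.0 - p_m1) * expit(i + cond.c_prime * x) + p_m1 * expit(
                i + cond.c_prime * x + cond.b
            )
            return float(np.sum(_W * py))

    return solve_intercept(cond.y_prevalence, marginal)


def true_moments(cond: Condition, i2: float) -> tuple[float, float]:
    """Population VAR(M) and COV(X,M) under the generating model."""
    if cond.mediator_type == CONTINUOUS:
        var_m = cond.a**2 * cond.var_x + cond.m_residual_sd**2
        cov_xm = cond.a * cond.var_x
        return float(var_m), float(cov_xm)
    sd_x = np.sqrt(cond.var_x)
    p_bar = _gh_expect(lambda z: expit(i2 + cond.a * sd_x * z))
    var_m = p_bar * (1.0 - p_bar)
    # COV(X,M) = E[X * P(M=1|X)] since E[X]=0
    cov_xm = _gh_expect(lambda z: sd_x * z * expit(i2 + cond.a * sd_x * z))
    return float(var_m), float(cov_xm)


def true_effects(cond: Condition) -> TruthRow:
    """Derive every method's true indirect effect and proportion mediated.

    The true values of the standardized estimators come from applying the
    standardization formulas to the true coefficients and true moments; the
    standardized-logistic and crude rows share the structural truth ``a*b``
    since that rescaling restores the direct-effect scale by construction.
    """
    a, b, cp = cond.a, cond.b, cond.c_prime
    i2 = mediator_intercept(cond)
    i3 = outcome_intercept(cond, i2)
    var_m, cov_xm = true_moments(cond, i2)

    ab = a * b
    s3 = std.sd_y3(cp, b, cond.var_x, var_m, cov_xm)
    sd_x = np.sqrt(cond.var_x)
    sd_m = np.sqrt(var_m)

    ie = {std.CRUDE: ab}
    pm_structural = ab / (ab + cp)
    pm = {std.CRUDE: pm_structural}

    if cond.mediator_type == BINARY:
        s2 = std.sd_m2(a, cond.var_x)
        ie[std.Y_STD] = (a / s2) * (b / s3)
        ie[std.FULL_STD] = (a * sd_x / s2) * (b * sd_m / s3)
        ie[POTENTIAL_OUTCOMES] = po_binary_log_or(i2, a, b)
    else:
        ie[std.Y_STD] = a * (b / s3)
        ie[std.FULL_STD] = (a * sd_x / sd_m) * (b * sd_m / s3)
        ie[std.STD_LOGISTIC] = ab
        pm[std.STD_LOGISTIC] = pm_structural
        ie[POTENTIAL_OUTCOMES] = ab

    pm[std.Y_STD] = pm_structural
    pm[std.FULL_STD] = pm_structural
    pm[POTENTIAL_OUTCOMES] = ie[POTENTIAL_OUTCOMES] / (ie[POTENTIAL_OUTCOMES] + cp)

    return TruthRow(
        condition=cond,
        i2_true=i2,
        i3_true=i3,
        var_m_true=var_m,
        cov_xm_true=cov_xm,
        ie_true=ie,
        pm_true=pm,
    )


def truth_table(conditions: list[Condition] | None = None) -> pd.DataFrame:
    """Long-format table of true indirect effects and proportions mediated."""
    conditions = conditions if conditions is not None else paper_conditions()
    records = []
    for cond in conditions:
        row = true_effects(cond)
        for method, ie in row.ie_true.items():
            records.append(
                {
                    "condition": cond.label,
                    "mediator_type": cond.mediator_type,
                    "m_prevalence": cond.m_prevalence,
                    "y_prevalence": cond.y_prevalence,
                    "method": method,
                    "ie_true": ie,
                    "pm_true": row.pm_true[method],
                    "i2_true": row.i2_true,
                    "i3_true": row.i3_true,
                    "var_m_true": row.var_m_true,
                    "cov_xm_true": row.cov_xm_true,
                }
            )
    return pd.DataFrame.from_records(records)
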