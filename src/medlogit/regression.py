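"""Path-model fitting for simple mediation with a binary outcome.

Three regression equations define the model:

* total-effect equation:   logit P(Y=1) = i1 + c*X
* mediator equation:       M = i2 + a*X (+ error)     [linear if M continuous,
                                                        logistic if M binary]
* direct-effect equation:  logit P(Y=1) = i3 + c'*X + b*M

Fitting is delegated to statsmodels (OLS for the linear mediator equation,
Newton-type maximum likelihood for the logistic equations); this module adds
validation, separation/convergence handling and the sample moments — VAR(X),
VAR(M), COV(X,M), and the linear-equation residual variance — that the
standardization formulas consume.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import statsmodels.api as sm

from .data import MediationDataset
from .exceptions import (
    ConvergenceError,
    DegenerateDesignError,
    InputError,
    SeparationError,
)

#: Gradient tolerance for logistic maximum likelihood.
LOGIT_TOL = 1e-8
#: Iteration cap for logistic maximum likelihood.
LOGIT_MAXITER = 100
#: A fitted log-odds coefficient beyond this magnitude is treated as
#: (quasi-)separation: the likelihood is still climbing toward infinity.
SEPARATION_BOUND = 15.0


@dataclass(frozen=True)
class LinearFit:
    """OLS fit of a simple linear regression, with residual variance on n-2."""

    intercept: float
    slope: float
    residual_variance: float


@dataclass(frozen=True)
class LogisticFit:
    """Maximum-likelihood logistic fit; ``slopes`` excludes the intercept."""

    intercept: float
    slopes: np.ndarray
    converged: bool
    iterations: int


@dataclass(frozen=True)
class PathFit:
    """All fitted path coefficients and the sample moments of one dataset.

    ``sigma2_mx`` is the residual variance of the linear mediator equation and
    exists only for a continuous mediator; logistic regression estimates no
    residual variance.
    """

    c: float
    a: float
    b: float
    c_prime: float
    i1: float
    i2: float
    i3: float
    sigma2_mx: float | None
    var_x: float
    var_m: float
    cov_xm: float
    mediator_type: str
    n: int


def fit_linear(x, m) -> LinearFit:
    """Ordinary least squares of ``m`` on ``x`` (the continuous-mediator equation).

    Raises
    ------
    DegenerateDesignError
        If ``x`` is constant.
    InputError
        On length mismatch or fewer than 3 observations.
    """
    x = np.asarray(x, dtype=float)
    m = np.asarray(m, dtype=float)
    if x.shape != m.shape or x.ndim != 1:
        raise InputError(f"x and m must be equal-length vectors, got {x.shape} and {m.shape}")
    if len(x) < 3:
        raise InputError(f"need at least 3 observations, got {len(x)}")
    if np.ptp(x) == 0 or np.var(x) < 1e-24 * max(1.0, np.mean(x) ** 2):
        raise DegenerateDesignError("exposure x is (numerically) constant; slope is not identified")
    res = sm.OLS(m, sm.add_constant(x)).fit()
    rss = float(np.sum(res.resid**2))
    return LinearFit(
        intercept=float(res.params[0]),
        slope=float(res.params[1]),
        residual_variance=rss / (len(x) - 2),
    )


def fit_logistic(design, y) -> LogisticFit:
    """Maximum-likelihood logistic regression of a 0/1 outcome on ``design``.

    ``design`` holds the predictor columns only; an intercept is always added.
    Newton iterations run to a gradient tolerance of ``LOGIT_TOL`` with at
    most ``LOGIT_MAXITER`` steps.

    Raises
    ------
    SeparationError
        If any coefficient diverges beyond ``SEPARATION_BOUND`` in absolute
        value (complete or quasi-complete separation).
    ConvergenceError
        If the iteration cap is hit before the gradient criterion is met.
    """
    design = np.asarray(design, dtype=float)
    if design.ndim == 1:
        design = design[:, None]
    y = np.asarray(y, dtype=float)
    if len(y) != len(design):
        raise InputError("design and y must have the same number of rows")
    classes = np.unique(y)
    if not np.array_equal(classes, [0.0, 1.0]):
        raise InputError(f"y must contain both 0 and 1 (and nothing else); found {classes.tolist()}")
    X = sm.add_constant(design, has_constant="add")
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # statsmodels warns en route to our own checks
            res = sm.Logit(y, X).fit(method="newton", tol=LOGIT_TOL, maxiter=LOGIT_MAXITER, disp=0)
    except np.linalg.LinAlgError as err:
        # Newton's Hessian goes singular when fitted probabilities saturate
        raise SeparationError(f"singular Hessian during Newton iterations: {err}") from err
    params = np.asarray(res.params, dtype=float)
    if np.any(np.abs(params) > SEPARATION_BOUND) or not np.all(np.isfinite(params)):
        raise SeparationError(
            f"coefficients diverged ({params.round(2).tolist()}); "
            "data show complete or quasi-complete separation"
        )
    converged = bool(res.mle_retvals.get("converged", False))
    if not converged:
        raise ConvergenceError(
            f"logistic fit did not converge within {LOGIT_MAXITER} iterations"
        )
    return LogisticFit(
        intercept=float(params[0]),
        slopes=params[1:],
        converged=converged,
        iterations=int(res.mle_retvals.get("iterations", -1)),
    )


def fit_paths(data: MediationDataset) -> PathFit:
    """Fit all three path equations and attach sample moments.

    The mediator equation is linear for a continuous mediator and logistic for
    a binary one.  Fitting failures are re-raised with a label naming the
    equation that failed.
    """
    x, m, y = data.x, data.m, data.y

    def _labelled(fitter, label, *args):
        try:
            return fitter(*args)
        except (SeparationError, ConvergenceError, DegenerateDesignError) as err:
            raise type(err)(f"{label}: {err}") from err

    total = _labelled(fit_logistic, "total-effect equation (Y~X)", x, y)
    if data.is_binary_mediator:
        med = _labelled(fit_logistic, "mediator equation (M~X)", x, m)
        i2, a = med.intercept, float(med.slopes[0])
        sigma2_mx = None
    else:
        med = _labelled(fit_linear, "mediator equation (M~X)", x, m)
        i2, a = med.intercept, med.slope
        sigma2_mx = med.residual_variance
    direct = _labelled(fit_logistic, "direct-effect equation (Y~X+M)", np.column_stack([x, m]), y)

    cov = np.cov(x, m, ddof=1)
    return PathFit(
        c=float(total.slopes[0]),
        a=a,
        b=float(direct.slopes[1]),
        c_prime=float(direct.slopes[0]),
        i1=total.intercept,
        i2=i2,
        i3=direct.intercept,
        sigma2_mx=sigma2_mx,
        var_x=float(cov[0, 0]),
        var_m=float(cov[1, 1]),
        cov_xm=float(cov[0, 1]),
        mediator_type=data.mediator_type,
        n=data.n,
    )
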