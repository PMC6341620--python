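"""Rescaling of logistic path coefficients across nested models.

Logistic coefficients are identified only up to the scale of a latent
continuous outcome whose error variance is fixed at pi^2/3 (the variance of
the standard logistic distribution).  Adding an outcome-predictive mediator
therefore inflates the latent-outcome variance and with it every coefficient
in the model — the "change of scales" that makes coefficients from the
total-effect and direct-effect equations incomparable.

Three rescalings restore comparability:

* **y-standardization** divides each coefficient by the latent SD of its
  equation's dependent variable, SD = sqrt(explained variance + pi^2/3).
* **full-standardization** additionally multiplies by the sample SD of the
  coefficient's own independent variable.
* the **standardized logistic solution** moves the total effect ``c`` onto the
  scale of the direct effect ``c'`` using the mediator-equation residual
  variance (continuous mediator only).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .data import BINARY, CONTINUOUS
from .exceptions import InputError, InvalidMomentsError, MethodNotApplicableError
from .regression import PathFit

#: Error variance of the standard logistic distribution, pi^2/3.
LOGISTIC_ERROR_VARIANCE = math.pi**2 / 3.0

CRUDE = "crude"
Y_STD = "y_std"
FULL_STD = "full_std"
STD_LOGISTIC = "std_logistic"


@dataclass(frozen=True)
class StandardizedPaths:
    """Path coefficients after one rescaling, plus the divisors used.

    ``sd_m2`` is the latent SD of the mediator equation and exists only when
    that equation is logistic (binary mediator); for a continuous mediator the
    mediator equation is linear and its ``a`` coefficient is already on an
    interpretable scale.
    """

    method: str
    c: float
    a: float
    b: float
    c_prime: float
    sd_y1: float
    sd_y3: float
    sd_m2: float | None = None


def sd_y1(c: float, var_x: float) -> float:
    """Latent SD of the outcome in the total-effect equation."""
    if var_x <= 0:
        raise InputError(f"var_x must be positive, got {var_x}")
    return math.sqrt(c * c * var_x + LOGISTIC_ERROR_VARIANCE)


def sd_m2(a: float, var_x: float) -> float:
    """Latent SD of a *binary* mediator's logistic equation."""
    if var_x <= 0:
        raise InputError(f"var_x must be positive, got {var_x}")
    return math.sqrt(a * a * var_x + LOGISTIC_ERROR_VARIANCE)


def sd_y3(c_prime: float, b: float, var_x: float, var_m: float, cov_xm: float) -> float:
    """Latent SD of the outcome in the direct-effect equation.

    The explained variance of the linear predictor c'X + bM is
    c'^2 VAR(X) + b^2 VAR(M) + 2 b c' COV(X,M).
    """
    radicand = (
        c_prime * c_prime * var_x
        + b * b * var_m
        + 2.0 * b * c_prime * cov_xm
        + LOGISTIC_ERROR_VARIANCE
    )
    if radicand <= 0:
        raise InvalidMomentsError(
            f"moments give a non-positive latent variance ({radicand}); "
            "var_x/var_m/cov_xm do not form a valid covariance structure"
        )
    return math.sqrt(radicand)


def y_standardize(fit: PathFit) -> StandardizedPaths:
    """Divide each coefficient by the latent SD of its equation's outcome.

    For a continuous mediator the ``a`` path comes from a linear regression
    and is left unchanged; for a binary mediator it is divided by the latent
    mediator SD.
    """
    s1 = sd_y1(fit.c, fit.var_x)
    s3 = sd_y3(fit.c_prime, fit.b, fit.var_x, fit.var_m, fit.cov_xm)
    if fit.mediator_type == BINARY:
        s2 = sd_m2(fit.a, fit.var_x)
        a = fit.a / s2
    else:
        s2 = None
        a = fit.a
    return StandardizedPaths(
        method=Y_STD,
        c=fit.c / s1,
        a=a,
        b=fit.b / s3,
        c_prime=fit.c_prime / s3,
        sd_y1=s1,
        sd_y3=s3,
        sd_m2=s2,
    )


def full_standardize(fit: PathFit) -> StandardizedPaths:
    """Multiply by the independent variable's SD, divide by the dependent's.

    Independent-variable SDs are the ordinary sample SDs of X and of the
    observed mediator.  Dependent-variable SDs are the latent SDs for the
    logistic equations; the continuous mediator's linear equation uses the
    observed SD of M as its dependent-variable scale.
    """
    sd_x = math.sqrt(fit.var_x)
    sd_m_obs = math.sqrt(fit.var_m)
    s1 = sd_y1(fit.c, fit.var_x)
    s3 = sd_y3(fit.c_prime, fit.b, fit.var_x, fit.var_m, fit.cov_xm)
    if fit.mediator_type == BINARY:
        s2 = sd_m2(fit.a, fit.var_x)
        a = fit.a * sd_x / s2
    else:
        s2 = None
        a = fit.a * sd_x / sd_m_obs
    return StandardizedPaths(
        method=FULL_STD,
        c=fit.c * sd_x / s1,
        a=a,
        b=fit.b * sd_m_obs / s3,
        c_prime=fit.c_prime * sd_x / s3,
        sd_y1=s1,
        sd_y3=s3,
        sd_m2=s2,
    )


def standardized_logistic_c(c: float, b: float, sigma2_mx: float | None) -> float:
    """Rescale the total effect ``c`` onto the direct-effect scale.

    Returns ``c * sqrt(1 + b^2 sigma2_mx / (pi^2/3))`` where ``sigma2_mx`` is
    the residual variance of the linear mediator equation.  Only defined for a
    continuous mediator, because logistic regression estimates no residual
    variance.
    """
    if sigma2_mx is None:
        raise MethodNotApplicableError(
            "the standardized logistic solution requires the mediator-equation "
            "residual variance and therefore a continuous mediator"
        )
    if sigma2_mx < 0:
        raise InputError(f"sigma2_mx must be non-negative, got {sigma2_mx}")
    return c * math.sqrt(1.0 + b * b * sigma2_mx / LOGISTIC_ERROR_VARIANCE)
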