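"""Indirect-effect and proportion-mediated estimators.

For each rescaling of the path coefficients (crude, y-standardized,
full-standardized, standardized-logistic) the indirect effect is computed
both as the product of coefficients ``a*b`` and as the difference of
coefficients ``c - c'``, and the proportion mediated by the three textbook
formulas ``ab/(ab+c')``, ``ab/c`` and ``1 - c'/c``.

The potential-outcomes row holds the natural indirect and direct effects.
With a continuous mediator and no exposure-mediator interaction the natural
indirect effect on the log-odds scale coincides exactly with the crude
``a*b``.  With a binary mediator the natural-effect odds ratio is

    OR_NIE = (1+exp(i2)) (1+exp(b+i2+a)) / [(1+exp(i2+a)) (1+exp(b+i2))]

with ``i2`` the mediator-equation intercept; the direct-effect log-OR is
``c'`` and the total effect is defined as their sum on the log scale, so all
three proportion-mediated formulas coincide for this method.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import standardization as std
from .data import BINARY, MediationDataset
from .exceptions import MethodNotApplicableError, UndefinedProportionError
from .regression import PathFit, fit_paths

POTENTIAL_OUTCOMES = "potential_outcomes"
#: Method rows in reporting order; std_logistic only applies to continuous M.
METHODS = (std.CRUDE, std.Y_STD, std.FULL_STD, std.STD_LOGISTIC, POTENTIAL_OUTCOMES)

AB_OVER_ABC = "ab_over_abc"
AB_OVER_C = "ab_over_c"
ONE_MINUS = "one_minus"
PM_FORMULAS = (AB_OVER_ABC, AB_OVER_C, ONE_MINUS)

#: Denominators smaller than this are treated as an undefined proportion.
_DENOM_EPS = 1e-12


@dataclass(frozen=True)
class EffectSet:
    """All effect estimates for one method applied to one dataset.

    Effects are on the log-odds (or rescaled) scale.  ``ie_difference`` is
    absent for the potential-outcomes method, whose total effect is defined
    as direct + indirect so the difference carries no extra information.
    ``inconsistent_mediation`` flags any proportion mediated outside [0, 1];
    the values themselves are never clipped.
    """

    method: str
    ie_product: float
    direct: float
    total: float
    pm_ab_over_abc: float | None
    ie_difference: float | None = None
    pm_ab_over_c: float | None = None
    pm_one_minus: float | None = None
    scale: str = "log_odds"
    inconsistent_mediation: bool = field(default=False, compare=False)


@dataclass(frozen=True)
class EffectTable:
    """One row per applicable method for one dataset."""

    rows: tuple[EffectSet, ...]
    n: int
    mediator_type: str

    def __post_init__(self):
        methods = [r.method for r in self.rows]
        if len(set(methods)) != len(methods):
            raise ValueError(f"duplicated method rows: {methods}")

    def row(self, method: str) -> EffectSet:
        for r in self.rows:
            if r.method == method:
                return r
        raise KeyError(method)

    def to_frame(self) -> pd.DataFrame:
        records = []
        for r in self.rows:
            records.append(
                {
                    "method": r.method,
                    "ie_product": r.ie_product,
                    "ie_difference": r.ie_difference,
                    "direct": r.direct,
                    "total": r.total,
                    "pm_ab_over_abc": r.pm_ab_over_abc,
                    "pm_ab_over_c": r.pm_ab_over_c,
                    "pm_one_minus": r.pm_one_minus,
                    "inconsistent_mediation": r.inconsistent_mediation,
                }
            )
        return pd.DataFrame.from_records(records)


def indirect_product(a: float, b: float) -> float:
    """Product-of-coefficients indirect effect, ``a*b``."""
    return a * b


def indirect_difference(c: float, c_prime: float) -> float:
    """Difference-of-coefficients indirect effect, ``c - c'`` (same metric)."""
    return c - c_prime


def proportion_mediated(ie: float, direct: float, total: float, formula: str) -> float:
    """One of the three proportion-mediated formulas.

    Raises
    ------
    UndefinedProportionError
        When the chosen formula's denominator is numerically zero.
    """
    if formula == AB_OVER_ABC:
        denom = ie + direct
    elif formula in (AB_OVER_C, ONE_MINUS):
        denom = total
    else:
        raise ValueError(f"unknown proportion-mediated formula {formula!r}")
    if abs(denom) < _DENOM_EPS:
        raise UndefinedProportionError(
            f"proportion mediated {formula}: denominator {denom} is numerically zero"
        )
    if formula == AB_OVER_ABC:
        return ie / denom
    if formula == AB_OVER_C:
        return ie / denom
    return 1.0 - direct / denom


def _pm_out_of_range(*values: float | None) -> bool:
    return any(v is not None and not (0.0 <= v <= 1.0) for v in values)


def _pm_or_none(ie: float, direct: float, total: float, formula: str) -> float | None:
    """Proportion mediated, or None when its denominator is degenerate.

    Row assembly must not abort a whole analysis over one undefined ratio;
    the simulation harness counts None as an excluded replicate.
    """
    try:
        return proportion_mediated(ie, direct, total, formula)
    except UndefinedProportionError:
        return None


def _regression_row(method: str, c: float, a: float, b: float, c_prime: float) -> EffectSet:
    """Assemble a crude/standardized row from one set of (rescaled) paths."""
    ie = indirect_product(a, b)
    diff = indirect_difference(c, c_prime)
    pm1 = _pm_or_none(ie, c_prime, c, AB_OVER_ABC)
    pm2 = _pm_or_none(ie, c_prime, c, AB_OVER_C)
    pm3 = _pm_or_none(ie, c_prime, c, ONE_MINUS)
    scale = "log_odds" if method in (std.CRUDE, std.STD_LOGISTIC) else "standardized"
    return EffectSet(
        method=method,
        ie_product=ie,
        ie_difference=diff,
        direct=c_prime,
        total=c,
        pm_ab_over_abc=pm1,
        pm_ab_over_c=pm2,
        pm_one_minus=pm3,
        scale=scale,
        inconsistent_mediation=_pm_out_of_range(pm1, pm2, pm3),
    )


def po_continuous(fit: PathFit) -> EffectSet:
    """Natural-effects row for a continuous mediator.

    The natural indirect effect equals ``a*b`` with ``a`` from the linear
    mediator equation and ``b`` from the logistic direct-effect equation; the
    natural direct effect is ``c'``; the total effect is their sum on the
    log-odds scale, so all proportion-mediated formulas agree.
    """
    if fit.mediator_type == BINARY:
        raise MethodNotApplicableError("po_continuous requires a continuous mediator")
    ie = indirect_product(fit.a, fit.b)
    total = ie + fit.c_prime
    pm = _pm_or_none(ie, fit.c_prime, total, AB_OVER_ABC)
    return EffectSet(
        method=POTENTIAL_OUTCOMES,
        ie_product=ie,
        direct=fit.c_prime,
        total=total,
        pm_ab_over_abc=pm,
        pm_ab_over_c=pm,
        pm_one_minus=pm,
        inconsistent_mediation=_pm_out_of_range(pm),
    )


def po_binary_log_or(i2: float, a: float, b: float) -> float:
    """Log of the natural-indirect-effect odds ratio for a binary mediator.

    Evaluated as a sum of ``log(1+exp(.))`` terms via ``logaddexp`` so large
    coefficients cannot overflow.
    """
    return float(
        np.logaddexp(0.0, i2)
        + np.logaddexp(0.0, b + i2 + a)
        - np.logaddexp(0.0, i2 + a)
        - np.logaddexp(0.0, b + i2)
    )


def po_binary(i2: float, a: float, b: float, c_prime: float) -> EffectSet:
    """Natural-effects row for a binary mediator (all effects log-odds)."""
    ie = po_binary_log_or(i2, a, b)
    total = ie + c_prime
    pm = _pm_or_none(ie, c_prime, total, AB_OVER_ABC)
    return EffectSet(
        method=POTENTIAL_OUTCOMES,
        ie_product=ie,
        direct=c_prime,
        total=total,
        pm_ab_over_abc=pm,
        pm_ab_over_c=pm,
        pm_one_minus=pm,
        inconsistent_mediation=_pm_out_of_range(pm),
    )


def effects_from_fit(fit: PathFit) -> EffectTable:
    """All applicable method rows computed from one fitted path model."""
    rows = [_regression_row(std.CRUDE, fit.c, fit.a, fit.b, fit.c_prime)]

    ys = std.y_standardize(fit)
    rows.append(_regression_row(std.Y_STD, ys.c, ys.a, ys.b, ys.c_prime))

    fs = std.full_standardize(fit)
    rows.append(_regression_row(std.FULL_STD, fs.c, fs.a, fs.b, fs.c_prime))

    if fit.mediator_type != BINARY:
        c_std = std.standardized_logistic_c(fit.c, fit.b, fit.sigma2_mx)
        rows.append(_regression_row(std.STD_LOGISTIC, c_std, fit.a, fit.b, fit.c_prime))
        rows.append(po_continuous(fit))
    else:
        rows.append(po_binary(fit.i2, fit.a, fit.b, fit.c_prime))

    return EffectTable(rows=tuple(rows), n=fit.n, mediator_type=fit.mediator_type)


def estimate_all(data: MediationDataset) -> EffectTable:
    """Fit the path model and compute every applicable estimator."""
    return effects_from_fit(fit_paths(data))
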