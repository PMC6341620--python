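"""Monte-Carlo evaluation of the mediation estimators.

For every condition the harness generates replicate datasets from the
structural model (standard-normal exposure; linear-normal or Bernoulli-logit
mediator; Bernoulli-logit outcome), runs every estimator on each replicate,
and scores each estimator against its own analytically derived true value
with

    bias = mean(estimate - truth)        MSE = mean((estimate - truth)^2)

Replicate streams are derived from a single master seed together with the
condition label and replicate index, so any subset of conditions or
replicates reproduces bit-identically and results do not depend on
execution order.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import expit

from .data import CONTINUOUS, MediationDataset
from .effects import EffectTable, effects_from_fit
from .exceptions import InputError, MedlogitError
from .regression import fit_paths
from .truth import Condition, TruthRow, true_effects

#: estimator column names inside each method row
IE_PRODUCT = "ie_product"
IE_DIFFERENCE = "ie_difference"
PM_ESTIMATORS = ("pm_ab_over_abc", "pm_ab_over_c", "pm_one_minus")
ESTIMATORS = (IE_PRODUCT, IE_DIFFERENCE) + PM_ESTIMATORS

#: abort threshold for failed replicates within a condition
MAX_FAILURE_FRACTION = 0.01


@dataclass(frozen=True)
class StudyConfig:
    """A simulation study: conditions, master seed, optional reps override."""

    conditions: tuple[Condition, ...]
    base_seed: int = 0
    reps: int | None = None

    def __post_init__(self):
        labels = [c.label for c in self.conditions]
        if len(set(labels)) != len(labels):
            raise InputError(f"duplicate condition labels: {labels}")


@dataclass(frozen=True)
class StudyResult:
    """Performance table plus per-condition fitted-path summaries."""

    performance: pd.DataFrame
    paths: pd.DataFrame
    truths: dict[str, TruthRow]


def replicate_seed(base_seed: int, label: str, rep: int) -> np.random.SeedSequence:
    """Independent, order-insensitive stream for one replicate."""
    return np.random.SeedSequence([int(base_seed), zlib.crc32(label.encode()), int(rep)])


def generate_dataset(cond: Condition, truth: TruthRow, seed) -> MediationDataset:
    """Draw one dataset of size ``cond.n`` from the generating model.

    ``seed`` may be anything ``numpy.random.default_rng`` accepts.  Draw
    order is fixed (X, then M, then Y) so a given stream always yields the
    same dataset.
    """
    if truth.condition != cond:
        raise InputError("truth row does not belong to this condition")
    rng = np.random.default_rng(seed)
    n = cond.n
    x = np.sqrt(cond.var_x) * rng.standard_normal(n)
    if cond.mediator_type == CONTINUOUS:
        m = truth.i2_true + cond.a * x + cond.m_residual_sd * rng.standard_normal(n)
    else:
        m = (rng.random(n) < expit(truth.i2_true + cond.a * x)).astype(float)
    y = (rng.random(n) < expit(truth.i3_true + cond.c_prime * x + cond.b * m)).astype(float)
    return MediationDataset(x=x, m=m, y=y, mediator_type=cond.mediator_type)


def evaluate(estimates, true_value: float) -> tuple[float, float]:
    """Bias and MSE of a list of replicate estimates against one truth."""
    arr = np.asarray(estimates, dtype=float)
    if arr.size == 0:
        raise InputError("no estimates to evaluate")
    if not np.all(np.isfinite(arr)):
        raise InputError("estimates contain non-finite values")
    dev = arr - float(true_value)
    return float(dev.mean()), float((dev**2).mean())


def _collect(table: EffectTable) -> dict[tuple[str, str], float | None]:
    """Flatten one replicate's effect table to (method, estimator) -> value."""
    out: dict[tuple[str, str], float | None] = {}
    for row in table.rows:
        out[(row.method, IE_PRODUCT)] = row.ie_product
        if row.ie_difference is not None:
            out[(row.method, IE_DIFFERENCE)] = row.ie_difference
        out[(row.method, "pm_ab_over_abc")] = row.pm_ab_over_abc
        out[(row.method, "pm_ab_over_c")] = row.pm_ab_over_c
        out[(row.method, "pm_one_minus")] = row.pm_one_minus
    return out


def _truth_for(truth: TruthRow, method: str, estimator: str) -> float:
    if estimator in (IE_PRODUCT, IE_DIFFERENCE):
        return truth.ie_true[method]
    return truth.pm_true[method]


def run_condition(
    cond: Condition, base_seed: int, reps: int | None = None
) -> tuple[TruthRow, pd.DataFrame, pd.DataFrame]:
    """Run one condition; returns (truth, performance rows, path summary).

    Replicates whose fit fails (separation, non-convergence) are logged and
    excluded; the condition aborts if more than ``MAX_FAILURE_FRACTION`` of
    replicates fail.  Replicates with an undefined proportion mediated are
    excluded from that estimator only, visible as a larger ``reps_failed``
    on its row.
    """
    truth = true_effects(cond)
    reps = reps if reps is not None else cond.reps
    values: dict[tuple[str, str], list[float]] = {}
    fitted: dict[str, list[float]] = {"a": [], "b": [], "c_prime": [], "c": []}
    failures: list[str] = []
    for rep in range(reps):
        data = generate_dataset(cond, truth, replicate_seed(base_seed, cond.label, rep))
        try:
            fit = fit_paths(data)
        except MedlogitError as err:
            failures.append(f"rep {rep}: {err}")
            continue
        for name in fitted:
            fitted[name].append(getattr(fit, name))
        for key, value in _collect(effects_from_fit(fit)).items():
            if value is not None:
                values.setdefault(key, []).append(value)
    if len(failures) > max(1, MAX_FAILURE_FRACTION * reps):
        detail = "; ".join(failures[:5])
        raise MedlogitError(
            f"condition {cond.label}: {len(failures)}/{reps} replicates failed ({detail} ...)"
        )

    perf_records = []
    for (method, estimator), vals in sorted(values.items()):
        bias, mse = evaluate(vals, _truth_for(truth, method, estimator))
        perf_records.append(
            {
                "condition": cond.label,
                "mediator_type": cond.mediator_type,
                "m_prevalence": np.nan if cond.m_prevalence is None else cond.m_prevalence,
                "y_prevalence": cond.y_prevalence,
                "method": method,
                "estimator": estimator,
                "true_value": _truth_for(truth, method, estimator),
                "bias": bias,
                "mse": mse,
                "reps_used": len(vals),
                "reps_failed": reps - len(vals),
            }
        )
    path_records = [
        {
            "condition": cond.label,
            "coefficient": name,
            "mean": float(np.mean(vals)),
            "sd": float(np.std(vals, ddof=1)) if len(vals) > 1 else 0.0,
            "reps": len(vals),
        }
        for name, vals in fitted.items()
    ]
    return truth, pd.DataFrame.from_records(perf_records), pd.DataFrame.from_records(path_records)


def run_study(config: StudyConfig) -> StudyResult:
    """Run every condition of a study and assemble the performance table."""
    perf_frames = []
    path_frames = []
    truths: dict[str, TruthRow] = {}
    for cond in config.conditions:
        truth, perf, paths = run_condition(cond, config.base_seed, config.reps)
        truths[cond.label] = truth
        perf_frames.append(perf)
        path_frames.append(paths)
    return StudyResult(
        performance=pd.concat(perf_frames, ignore_index=True),
        paths=pd.concat(path_frames, ignore_index=True),
        truths=truths,
    )
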