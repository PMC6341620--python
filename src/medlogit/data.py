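"""The unit of analysis: one subject-level dataset for a simple mediation model.

A :class:`MediationDataset` carries the exposure ``x`` (continuous), the
mediator ``m`` (continuous, or 0/1 coded) and the binary outcome ``y`` for
``n`` subjects.  The mediator type is an explicit tag, never inferred from the
values, because it decides which regression family fits the mediator equation
and which estimators are applicable downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .exceptions import InputError

CONTINUOUS = "continuous"
BINARY = "binary"
MEDIATOR_TYPES = (CONTINUOUS, BINARY)

MIN_N = 10


def _as_clean_vector(values, name: str) -> np.ndarray:
    arr = np.asarray(values, dtype=float)
    if arr.ndim != 1:
        raise InputError(f"{name} must be one-dimensional, got shape {arr.shape}")
    if not np.all(np.isfinite(arr)):
        raise InputError(f"{name} contains missing or non-finite values")
    return arr


def _check_binary(arr: np.ndarray, name: str) -> None:
    values = np.unique(arr)
    bad = values[~np.isin(values, (0.0, 1.0))]
    if bad.size:
        raise InputError(
            f"{name} must contain only 0 and 1; found value(s) {bad.tolist()}"
        )
    if values.size < 2:
        raise InputError(f"{name} must contain both 0 and 1; found only {values.tolist()}")


@dataclass(frozen=True)
class MediationDataset:
    """Validated per-subject data for one simple mediation analysis.

    Parameters
    ----------
    x : array-like of float
        Exposure values, one per subject.
    m : array-like of float
        Mediator values; strictly 0/1 when ``mediator_type`` is ``"binary"``.
    y : array-like of float
        Outcome values, strictly 0/1 with both classes present.
    mediator_type : {"continuous", "binary"}
        How the mediator equation is to be fitted (linear vs logistic) and
        which estimators apply.
    """

    x: np.ndarray
    m: np.ndarray
    y: np.ndarray
    mediator_type: str
    n: int = field(init=False)

    def __post_init__(self):
        if self.mediator_type not in MEDIATOR_TYPES:
            raise InputError(
                f"mediator_type must be one of {MEDIATOR_TYPES}, got {self.mediator_type!r}"
            )
        x = _as_clean_vector(self.x, "x")
        m = _as_clean_vector(self.m, "m")
        y = _as_clean_vector(self.y, "y")
        if not (len(x) == len(m) == len(y)):
            raise InputError(
                f"x, m, y must have equal length; got {len(x)}, {len(m)}, {len(y)}"
            )
        if len(x) < MIN_N:
            raise InputError(f"need at least {MIN_N} subjects, got {len(x)}")
        _check_binary(y, "y")
        if self.mediator_type == BINARY:
            _check_binary(m, "m (binary mediator)")
        for name, arr in (("x", x), ("m", m), ("y", y)):
            arr.setflags(write=False)
            object.__setattr__(self, name, arr)
        object.__setattr__(self, "n", len(x))

    @property
    def is_binary_mediator(self) -> bool:
        return self.mediator_type == BINARY
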