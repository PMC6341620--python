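"""Exception hierarchy.

All medlogit errors derive from :class:`MedlogitError` so callers can catch
one base class; input problems and numerical problems are distinguished so
the CLI can map them to different exit codes.
"""


class MedlogitError(Exception):
    """Base class for all medlogit errors."""


class InputError(MedlogitError):
    """Invalid user input: bad vectors, bad columns, bad file contents."""


class DegenerateDesignError(MedlogitError):
    """The design matrix is rank deficient (e.g. a constant exposure)."""


class SeparationError(MedlogitError):
    """Complete or quasi-complete separation: logistic ML diverges."""


class ConvergenceError(MedlogitError):
    """The iterative fitter stopped without meeting its gradient criterion."""


class MethodNotApplicableError(MedlogitError):
    """An estimator was requested for a mediator type it is not defined for."""


class UndefinedProportionError(MedlogitError):
    """A proportion-mediated denominator is (numerically) zero."""


class InvalidMomentsError(MedlogitError):
    """Sample moments do not form a valid covariance structure."""
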