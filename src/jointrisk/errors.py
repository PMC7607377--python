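"""Exception hierarchy.

All package-raised errors derive from :class:`JointriskError` so callers can
catch one base class; the CLI maps subclasses to exit codes (validation -> 2,
registry -> 3).
"""


class JointriskError(Exception):
    """Base class for all errors raised by jointrisk."""


class ValidationError(JointriskError):
    """Invalid input data or arguments.

    Carries an optional ``fields`` mapping of field name -> reason so callers
    can report every problem at once rather than the first one found.
    """

    def __init__(self, message: str, fields: dict[str, str] | None = None):
        super().__init__(message)
        self.fields = dict(fields or {})


class DegenerateKnotsError(ValidationError):
    """Too few distinct values to place the requested knots."""


class UnfittableError(JointriskError):
    """Dataset cannot support a fit (e.g. no observed events)."""


class ConvergenceError(JointriskError):
    """Optimiser failed to converge; carries the last iterate for diagnosis."""

    def __init__(self, message: str, last_model=None, grad_norm: float | None = None):
        super().__init__(message)
        self.last_model = last_model
        self.grad_norm = grad_norm


class BundleFormatError(JointriskError):
    """Malformed or version-incompatible coefficient-bundle file."""


class RegistryLookupError(JointriskError):
    """No model bundle matches the requested key."""


class RegistryIntegrityError(JointriskError):
    """Registry or bundle violates a structural invariant."""


class UndefinedMetricError(JointriskError):
    """A metric has no defined value on the given data (e.g. no usable pairs)."""
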