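"""Exception hierarchy shared across the package.

The CLI maps :class:`DomainError` / :class:`ValidationError` /
:class:`ModelViolationError` to exit code 1 and :class:`NumericalError`
to exit code 2.
"""


class ValidRiskError(Exception):
    """Base class for all package errors."""


class DomainError(ValidRiskError, ValueError):
    """An input lies outside the mathematical domain of an operation."""


class ValidationError(ValidRiskError, ValueError):
    """Malformed user-supplied tabular or configuration input."""


class ModelViolationError(ValidRiskError, ValueError):
    """Input is inconsistent with the model family (e.g. DZ pairs more
    similar than MZ pairs under an additive-plus-shared-environment model)."""


class NumericalError(ValidRiskError, RuntimeError):
    """A root-find, quadrature or estimation step failed to converge or is
    degenerate."""
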