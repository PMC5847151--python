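"""Exception hierarchy.

All package errors derive from :class:`ShoalHMMError` so callers can catch
one base class; the subclasses mirror the distinct failure modes of the
pipeline (bad files, bad parameters, quantities that are mathematically
undefined for the given input, and numerical degeneracies).
"""


class ShoalHMMError(Exception):
    """Base class for all package-specific errors."""


class MalformedInputError(ShoalHMMError, ValueError):
    """An input file or table violates the documented contract."""


class ParameterError(ShoalHMMError, ValueError):
    """A function argument is outside its documented domain."""


class ConfigurationError(ShoalHMMError, ValueError):
    """A configuration object is internally inconsistent."""


class UndefinedResultError(ShoalHMMError, ArithmeticError):
    """The requested quantity is undefined for this input (e.g. zero variance)."""


class NumericalDegeneracyError(ShoalHMMError, ArithmeticError):
    """A numerical routine met a degenerate case (e.g. reducible chain)."""
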