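"""Exception hierarchy.

All errors derive from :class:`PetnormError` so callers can catch the
package's failures with one clause; each subclass also derives from the
closest builtin so idiomatic ``except ValueError`` still works.
"""


class PetnormError(Exception):
    """Base class for all petnorm errors."""


class ConfigurationError(PetnormError, ValueError):
    """Invalid parameters or study design (e.g. fewer than 2 subjects)."""


class ValidationError(PetnormError, ValueError):
    """Input data violates a precondition (e.g. empty mask, negative FWHM)."""


class DimensionError(PetnormError, ValueError):
    """Grid shapes or crop windows are incompatible."""


class FormatError(PetnormError, ValueError):
    """A file is not a readable 3D NIfTI-1 volume."""


class NumericalDomainError(PetnormError, ArithmeticError):
    """A computation hit an undefined value (division by zero inside a mask)."""
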