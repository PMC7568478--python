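"""Exception hierarchy shared across the pipeline.

Validation problems (bad inputs, impossible configurations, pedigree
integrity) raise :class:`ValidationError`; numerical failures during
fitting raise :class:`NumericalError`.  The CLI maps these to exit
codes 2 and 3 respectively.
"""


class QuantheritError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(QuantheritError, ValueError):
    """Invalid input data or configuration."""


class PedigreeError(ValidationError):
    """Pedigree integrity violation (e.g. an individual is its own parent)."""


class NumericalError(QuantheritError, RuntimeError):
    """A solver failed or produced an undefined result."""
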