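"""Exception hierarchy."""


class DietFrailError(Exception):
    """Base class for package errors."""


class ConfigurationError(DietFrailError):
    """A required column, taxonomy entry or config key is missing or invalid."""


class ParameterError(DietFrailError):
    """An operation was called with out-of-domain parameters."""


class DataValidationError(DietFrailError):
    """Input data violate a structural invariant (grid gaps, range errors)."""


class FitError(DietFrailError):
    """A model fit failed (degenerate design, non-convergence)."""
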