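"""Exception hierarchy shared across the package."""


class HemovisError(Exception):
    """Base class for all package errors."""


class ParameterError(HemovisError, ValueError):
    """A function argument is outside its valid domain."""


class ValidationError(HemovisError, ValueError):
    """Data violate a structural invariant (shape, sign, ordering)."""


class FormatError(HemovisError, ValueError):
    """A file does not parse as the expected on-disk format."""


class DegenerateInputError(HemovisError, ValueError):
    """Input is structurally valid but admits no meaningful result."""


class ConfigurationError(HemovisError, ValueError):
    """A configuration value or combination is invalid."""


class MissingDataError(HemovisError, ValueError):
    """Required data are entirely missing (e.g. an all-NaN trace)."""


class EmptyConditionError(HemovisError, ValueError):
    """No usable trials remain for a condition after artifact rejection."""


class EmptyMontageError(HemovisError, ValueError):
    """No channels survive pruning / selection."""
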