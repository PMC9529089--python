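class GiftError(Exception):
    """Base class for all pipeline errors."""


class InvalidParameterError(GiftError, ValueError):
    """A processing parameter or input violates its contract."""


class InsufficientDataError(GiftError):
    """Not enough measured distances / populated bins to estimate a diameter."""
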