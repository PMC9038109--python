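"""Exception hierarchy shared across the package."""


class OsteocountError(Exception):
    """Base class for package errors."""


class ValidationError(OsteocountError, ValueError):
    """An input violates a documented invariant."""


class FormatError(OsteocountError, ValueError):
    """A file does not follow the expected layout."""


class ConfigError(OsteocountError, ValueError):
    """A configuration file or option set is invalid."""


class DegenerateImageError(OsteocountError, ValueError):
    """An image has no usable intensity structure (e.g. constant grayscale)."""


class CapacityError(OsteocountError, RuntimeError):
    """A synthetic scene could not fit the requested objects."""

    def __init__(self, message: str, placed: int = 0):
        super().__init__(message)
        self.placed = placed
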