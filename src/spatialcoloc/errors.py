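"""Exception hierarchy for input validation and file-format problems."""


class SpatialColocError(Exception):
    """Base class for all package-specific errors."""


class FormatError(SpatialColocError):
    """A file does not conform to the expected on-disk format."""


class ValidationError(SpatialColocError):
    """Input values violate a domain invariant."""
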