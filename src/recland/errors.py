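"""Exception types shared across the package."""


class RecLandError(Exception):
    """Base class for all package-specific errors."""


class MapFormatError(RecLandError, ValueError):
    """A genetic-map file violates the expected TSV layout or ordering."""


class ParameterError(RecLandError, ValueError):
    """A caller/config parameter combination is invalid."""


class EmptyInputError(RecLandError, ValueError):
    """An operation received an empty input it cannot handle."""
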