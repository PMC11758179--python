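"""Exception hierarchy shared across the package."""


class PexvoteError(Exception):
    """Base class for all package-specific errors."""


class SchemaError(PexvoteError):
    """An input table is missing a required column or has the wrong shape."""


class ValidationError(PexvoteError):
    """Values are present but violate a contract (vocabulary, range, uniqueness)."""


class ParseError(PexvoteError):
    """A cell could not be parsed as the required type."""


class MissingMarkerError(PexvoteError):
    """A patient lacks a measurement required by a marker rule."""
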