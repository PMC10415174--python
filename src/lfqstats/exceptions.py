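"""Exception hierarchy shared across the package."""


class LfqstatsError(Exception):
    """Base class for all package-specific errors."""


class FormatError(LfqstatsError):
    """A file does not conform to the expected dialect/format."""


class AmbiguousFormatError(FormatError):
    """More than one engine dialect matches the file header."""

    def __init__(self, candidates):
        self.candidates = sorted(candidates)
        super().__init__(
            "header matches multiple dialects: " + ", ".join(self.candidates)
        )


class UnrecognizedFormatError(FormatError):
    """No known engine dialect matches the file header."""


class ParseError(LfqstatsError):
    """A cell or line could not be parsed as the expected type."""


class JoinError(LfqstatsError):
    """Sample metadata and intensity table could not be joined."""
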