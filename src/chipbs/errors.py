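"""Package-wide exception types."""


class ChipBsError(Exception):
    """Base class for all chipbs errors."""


class SizingError(ChipBsError):
    """Requested synthetic elements do not fit in the requested genome."""


class ParseError(ChipBsError):
    """A malformed input file; carries file name and line number."""

    def __init__(self, message: str, filename: str | None = None, line: int | None = None):
        loc = ""
        if filename is not None:
            loc = f" [{filename}" + (f":{line}" if line is not None else "") + "]"
        super().__init__(message + loc)
        self.filename = filename
        self.line = line


class NoConversionControlError(ChipBsError):
    """No coverage on the spike-in contig: conversion rate cannot be estimated."""


class ParameterError(ChipBsError):
    """An invalid analysis parameter (non-positive window, empty group, ...)."""
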