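"""Exception types shared across the package."""


class NucolocError(Exception):
    """Base class for all package errors."""


class FormatError(NucolocError):
    """A localization table is missing a required column or is malformed."""


class ParseError(NucolocError):
    """A table cell could not be parsed; carries the offending row number."""

    def __init__(self, message: str, row: int | None = None):
        super().__init__(message)
        self.row = row


class ParameterError(NucolocError):
    """An analysis parameter is out of its valid range."""


class PairingError(NucolocError):
    """Paired samples have mismatched lengths or cannot be paired."""


class SegmentationError(NucolocError):
    """Nuclear segmentation found no usable foreground."""


class PlacementError(NucolocError):
    """Synthetic foci could not be placed without overlap."""


class UndefinedResultError(NucolocError):
    """A coefficient is undefined for this input (zero variance or energy)."""


class FitRejectedError(NucolocError):
    """A candidate spot was rejected during Gaussian fitting (non-fatal)."""
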