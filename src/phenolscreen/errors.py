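"""Exception hierarchy for the screen pipeline.

Every stage raises a subclass of :class:`ScreenError`, so callers (and the
CLI) can map error classes to exit codes without string matching.
"""


class ScreenError(Exception):
    """Base class for all pipeline errors."""


class ParseError(ScreenError):
    """A file could not be parsed; carries the offending line number when known."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


class LayoutError(ScreenError):
    """Plate layout violates an invariant (e.g. wild-type position unmapped)."""


class DuplicatePositionError(LayoutError):
    """The same (row, col) appears twice in a layout file."""


class DuplicateTermError(ParseError):
    """A gene-set file defines the same term id twice."""


class ConfigError(ScreenError):
    """Invalid configuration value; message names the key path."""


class GridDetectionError(ScreenError):
    """The spot grid could not be located in a plate image."""


class MissingDataError(ScreenError):
    """No usable measurement remains for a strain after quality filtering."""


class UndefinedGSVError(ScreenError):
    """GSV undefined because the untreated density is zero or flagged."""


class PlateNormalizationError(ScreenError):
    """Wild-type reference densities unusable; the whole plate is rejected."""


class NoValidConcentrationError(ScreenError):
    """No candidate concentration satisfies the growth constraint."""


class EmptyMatrixError(ScreenError):
    """Profile matrix construction received no usable rows."""


class EmptyInputError(ScreenError):
    """A pipeline stage received an empty input collection."""


class ExtrapolationError(ScreenError):
    """Requested inhibition level lies outside the observed dose range."""


class FitError(ScreenError):
    """A nonlinear fit failed to converge."""
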