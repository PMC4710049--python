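"""Exception hierarchy shared across the package."""


class XYSpotError(Exception):
    """Base class for all package-specific errors."""


class ParameterError(XYSpotError, ValueError):
    """A parameter is outside its valid domain."""


class PlacementError(XYSpotError, RuntimeError):
    """Hard-core nucleus placement failed within the attempt budget."""


class SpotBoundsError(XYSpotError, ValueError):
    """One or more spot records fall outside the image bounds.

    ``rows`` holds the offending record indices.
    """

    def __init__(self, rows, message=None):
        self.rows = list(rows)
        super().__init__(message or f"spot coordinates out of bounds at rows {self.rows}")


class ConsistencyError(XYSpotError, ValueError):
    """Cross-referenced records disagree (e.g. a spot cites an unknown cell)."""


class AlignmentError(XYSpotError, ValueError):
    """Homolog alignment input is malformed (unequal lengths, empty side)."""


class GeometryError(XYSpotError, ValueError):
    """Degenerate landmark geometry for the dorsoventral border."""


class EmptyFieldError(XYSpotError, ValueError):
    """A purity field has no unmasked pixels to summarize."""


class UndefinedRateError(XYSpotError, ZeroDivisionError):
    """A rate or ratio is undefined because its denominator is zero."""


class ConfigError(XYSpotError, ValueError):
    """A run configuration is invalid (unknown key, missing required value)."""
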