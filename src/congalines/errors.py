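"""Exception hierarchy.

All package-specific errors derive from :class:`CongaLinesError` so callers
can catch one base class at the CLI boundary.
"""


class CongaLinesError(Exception):
    """Base class for all errors raised by congalines."""


class InvalidWindowError(CongaLinesError, ValueError):
    """Window polygon is degenerate, self-intersecting or has zero area."""


class InvalidStrainError(CongaLinesError, ValueError):
    """Strain estimate violates R >= 1."""


class InvalidMaskError(CongaLinesError, ValueError):
    """Mask polygon falls outside the window exterior or splits the window."""


class InvalidParameterError(CongaLinesError, ValueError):
    """Process or search parameter outside its admissible range."""


class InsufficientDataError(CongaLinesError, ValueError):
    """Too few points / discs for the requested operation."""


class UndefinedBearingError(CongaLinesError, ValueError):
    """Bearing requested between coincident points."""


class PlacementError(CongaLinesError, RuntimeError):
    """A planted chain could not be placed inside the window."""


class FitFailureError(CongaLinesError, RuntimeError):
    """Model fit did not converge; carries diagnostics in ``.diagnostics``."""

    def __init__(self, message: str, diagnostics=None):
        super().__init__(message)
        self.diagnostics = diagnostics


class SchemaError(CongaLinesError, ValueError):
    """Input file does not match the documented schema."""


class UnsupportedGeometryError(CongaLinesError, ValueError):
    """GeoJSON geometry type other than Polygon."""
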