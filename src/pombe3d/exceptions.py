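"""Package exception hierarchy.

All errors raised by pombe3d derive from :class:`Pombe3dError` so callers can
catch the package's failures with a single ``except`` clause.
"""


class Pombe3dError(Exception):
    """Base class for all pombe3d errors."""


class GeometryError(Pombe3dError, ValueError):
    """Invalid nuclear geometry (e.g. nucleolus protruding outside the nucleus)."""


class CoordinateError(Pombe3dError, ValueError):
    """A genomic coordinate is outside its chromosome or names an unknown chromosome."""


class ContactParseError(Pombe3dError, ValueError):
    """A contact TSV line could not be parsed; carries the 1-based line number."""

    def __init__(self, message: str, line_number: int | None = None):
        self.line_number = line_number
        if line_number is not None:
            message = f"line {line_number}: {message}"
        super().__init__(message)


class ConfigurationError(Pombe3dError, ValueError):
    """A configuration value is out of its admissible range."""


class CalibrationError(Pombe3dError, RuntimeError):
    """The contact-fraction calibration could not reach the target radius of gyration."""


class InitializationError(Pombe3dError, RuntimeError):
    """Chain placement failed (geometry too crowded for a self-avoiding walk)."""


class FeatureError(Pombe3dError, ValueError):
    """A feature track or granule signal violates its contract."""
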