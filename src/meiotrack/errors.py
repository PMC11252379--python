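"""Exception types shared across the package."""


class MeiotrackError(Exception):
    """Base class for all package-specific errors."""


class SchemaError(MeiotrackError, ValueError):
    """A required column or field is missing from an input table."""


class TrackFormatError(MeiotrackError, ValueError):
    """A track table violates the format contract (e.g. duplicate timestamps)."""


class ConfigurationError(MeiotrackError, ValueError):
    """Inconsistent or incomplete analysis configuration."""


class ParameterError(MeiotrackError, ValueError):
    """A simulation or model parameter is out of its valid range."""


class GeometryError(MeiotrackError, ValueError):
    """Invalid nuclear geometry (e.g. nucleolus outside the envelope)."""


class DriftReferenceError(MeiotrackError, RuntimeError):
    """No somatic reference tracks available for drift correction."""
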