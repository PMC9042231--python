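"""Exception hierarchy shared across the package."""


class EthoflightError(Exception):
    """Base class for all package-specific errors."""


class PoseFormatError(EthoflightError):
    """A pose file does not conform to a supported dialect (e.g. a body part
    is missing or a header row is malformed)."""


class PoseDataError(EthoflightError):
    """A pose file parsed, but its contents violate a data invariant
    (non-monotonic frame index, no valid frames, ...)."""


class GeometryError(EthoflightError):
    """Arena geometry is internally inconsistent (shelter outside the arena,
    simulated start position inside the shelter, ...)."""


class ConfigError(EthoflightError):
    """A configuration file or analysis setup is invalid: unknown keys, missing
    required regions, epochs outside the session, and similar."""


class SchemaError(EthoflightError):
    """A results table cannot be written because the records are empty or
    do not share a homogeneous schema."""
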