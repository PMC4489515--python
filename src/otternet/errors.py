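"""Exception types shared across the package."""


class OtternetError(Exception):
    """Base class for all package-specific errors."""


class ParameterError(OtternetError, ValueError):
    """A parameter value violates its documented domain."""


class FormatError(OtternetError, ValueError):
    """A serialized network file is malformed; message carries context."""


class CapacityError(OtternetError, RuntimeError):
    """The landscape cannot host the requested configuration
    (e.g. no non-overlapping placement for a female core area)."""


class ConfigurationError(OtternetError, ValueError):
    """A scenario or engine configuration is internally inconsistent."""
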