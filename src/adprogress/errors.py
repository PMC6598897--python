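"""Exception hierarchy shared across the package."""


class AdprogressError(Exception):
    """Base class for all package-specific errors."""


class SchemaError(AdprogressError):
    """An input table is missing required columns or has the wrong layout."""


class ValidationError(AdprogressError):
    """Row-level content violates a dataset invariant."""


class ConfigurationError(AdprogressError):
    """A model / pipeline configuration is internally inconsistent."""


class DegenerateTransformError(AdprogressError):
    """A percentile transform cannot be fitted (e.g. all-identical values)."""
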