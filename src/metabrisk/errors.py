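"""Exception hierarchy shared across the pipeline."""


class MetabriskError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(MetabriskError, ValueError):
    """A configuration object violates its invariants."""


class InputError(MetabriskError, ValueError):
    """Data handed to an operation violates its preconditions."""
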