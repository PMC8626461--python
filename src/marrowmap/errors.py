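"""Exception hierarchy shared across the pipeline."""


class MarrowMapError(Exception):
    """Base class for all package errors."""


class ConfigurationError(MarrowMapError):
    """Invalid or missing configuration (unknown stage, missing spacing, bad schema)."""


class FormatError(MarrowMapError):
    """File content does not match the declared contract (channel counts, columns)."""


class ValidationError(MarrowMapError):
    """Data violates a documented invariant (negative radius, empty input)."""


class DependencyError(MarrowMapError):
    """A pipeline stage's required input is absent."""


class GenerationError(MarrowMapError):
    """Synthetic-data generation cannot satisfy the requested geometry."""


class GatingError(MarrowMapError):
    """Automatic intensity gating is not possible on the given data."""
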