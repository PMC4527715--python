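"""Exception hierarchy for the envepi pipeline."""


class EnvepiError(Exception):
    """Base class for all envepi errors."""


class ConfigError(EnvepiError):
    """Invalid configuration (bad proportions, thresholds, paths)."""


class SchemaError(EnvepiError):
    """Input table does not match the declared column schema."""


class ParseError(EnvepiError):
    """Non-numeric or otherwise unreadable cell in an input table."""


class InsufficientReplicationError(EnvepiError):
    """A test condition has fewer than the minimum number of replicates."""


class NormalizationError(EnvepiError):
    """Normalization is ill-posed for the given data (e.g. zero reference)."""


class ZeroVarianceError(EnvepiError):
    """Features with zero variance across samples where variance is required."""


class NoLogPhaseError(EnvepiError):
    """No window of a growth curve satisfies the log-phase fit criteria."""


class DegenerateFitError(EnvepiError):
    """Degenerate input for a distribution fit (e.g. all degrees equal)."""
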