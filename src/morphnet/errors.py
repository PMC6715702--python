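"""Exception hierarchy shared across the pipeline stages."""


class MorphnetError(Exception):
    """Base class for all package-specific errors."""


class InvalidMeasurementError(MorphnetError):
    """A raw measurement violates its physical constraints (sign, bounds)."""


class CohortValidationError(MorphnetError):
    """A cohort table breaks a structural invariant (duplicate IDs, bad metadata)."""


class NormalizationError(MorphnetError):
    """A normalization denominator is unusable for one or more scans."""


class NetworkError(MorphnetError):
    """Correlation-network construction failed a precondition."""


class ClusteringError(MorphnetError):
    """Markov clustering received an invalid graph or parameter set."""


class StatsError(MorphnetError):
    """An enrichment or risk statistic received out-of-bounds counts."""


class ConfigError(MorphnetError):
    """A configuration file or object is malformed."""
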