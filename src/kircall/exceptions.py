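"""Exception and warning hierarchy for kircall."""


class KircallError(Exception):
    """Base class for all kircall errors."""


class FastaError(KircallError):
    """Malformed or unusable FASTA input."""


class ConfigError(KircallError):
    """Invalid configuration (categories, rules, simulation parameters)."""


class ParameterError(KircallError, ValueError):
    """Invalid parameter value passed to an operation."""


class NormalizationError(KircallError):
    """Sample cannot be normalized (e.g. no background coverage)."""


class DensityError(KircallError):
    """Population density is degenerate or based on too few samples."""


class ThresholdError(KircallError):
    """Peak structure incompatible with the gene's declared category."""


class KircallWarning(UserWarning):
    """Base class for kircall warnings."""
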