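"""Exception hierarchy for the pbrtqc package."""


class PBRTQCError(Exception):
    """Base class for all pbrtqc errors."""


class ConfigurationError(PBRTQCError):
    """A parameter value or parameter combination is invalid or infeasible."""


class InputError(PBRTQCError):
    """Input data do not satisfy an operation's preconditions."""


class DegenerateDataError(PBRTQCError):
    """Data are degenerate for the requested fit (e.g. constant series)."""


class OptimizationError(PBRTQCError):
    """Grid search produced no usable candidate configuration."""
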