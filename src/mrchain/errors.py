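"""Exception hierarchy for mrchain."""


class MrChainError(Exception):
    """Base class for all mrchain errors."""


class ConfigError(MrChainError):
    """A configuration value is out of its valid range; the message names the field."""


class FormatError(MrChainError):
    """An input file does not conform to the expected tabular layout."""


class ValidationError(MrChainError):
    """Input data violate a record-level invariant."""


class InsufficientInstrumentsError(MrChainError):
    """Fewer instruments than the estimator's minimum."""


class EstimationError(MrChainError):
    """Numerical estimation failed (non-convergence or degenerate design)."""
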