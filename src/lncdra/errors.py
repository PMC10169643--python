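"""Exception hierarchy; exit codes used by the CLI are attached per class."""


class LncdraError(Exception):
    """Base class for package errors."""
    exit_code = 1


class ConfigError(LncdraError):
    """Invalid configuration value or unknown key."""
    exit_code = 2


class ParseError(LncdraError):
    """Malformed input row; message names the line number."""
    exit_code = 3


class IntegrityError(LncdraError):
    """Contradictory duplicate records or empty input."""
    exit_code = 3


class DegenerateInputError(LncdraError):
    """Input on which a quantity is mathematically undefined (e.g. all-zero
    association matrix, for which the GIP bandwidth would divide by zero)."""
    exit_code = 3


class ContractError(LncdraError):
    """Shape or precondition violation between components."""
    exit_code = 3


class FoldError(LncdraError):
    """Cross-validation split cannot be constructed."""
    exit_code = 3


class MetricError(LncdraError):
    """Metrics undefined (e.g. single-class labels)."""
    exit_code = 3


class MaskError(LncdraError):
    """Edge-masking precondition violation."""
    exit_code = 3


class CheckpointError(LncdraError):
    """Checkpoint inconsistent with the data it is applied to."""
    exit_code = 3


class DivergenceError(LncdraError):
    """Non-finite loss during optimization; message names the epoch."""
    exit_code = 4
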