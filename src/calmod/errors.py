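"""Exception types shared across the pipeline."""


class CalmodError(Exception):
    """Base class for all calmod errors."""


class ContractError(CalmodError, ValueError):
    """An operation was called with inputs violating its contract."""


class InvalidConfigError(CalmodError, ValueError):
    """A configuration value is out of its admissible range."""


class MissingNeuropilError(ContractError):
    """Neuropil subtraction requested for a trace without a paired neuropil signal."""


class NonPositiveBaselineError(CalmodError, ValueError):
    """The estimated baseline F0 is not positive (wrong input units or offsets)."""


class LoadError(CalmodError, ValueError):
    """A session file failed schema validation; the message carries row/field context."""


class PipelineError(CalmodError, RuntimeError):
    """A pipeline stage failed; the message names the stage."""
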