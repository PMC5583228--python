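"""Exception types shared across the package.

Every error deliberately carries enough context (field, dataset, stage,
subject/session) to be actionable from a pipeline log.
"""


class WMEntropyError(Exception):
    """Base class for all package errors."""


class ConfigurationError(WMEntropyError, ValueError):
    """A configuration field is invalid; the message names the field."""


class UnsupportedInputError(WMEntropyError, ValueError):
    """Input shape/content outside the operation's domain (e.g. single channel)."""


class EmptyInputError(WMEntropyError, ValueError):
    """An operation received an empty collection where data is required."""


class EmptyResultError(WMEntropyError, RuntimeError):
    """A filtering step removed everything (e.g. all trials rejected)."""


class FormatError(WMEntropyError, ValueError):
    """A fixture container is malformed; the message names the offending dataset."""


class DegenerateInputError(WMEntropyError, ValueError):
    """Mathematically degenerate input (all-zero spectrum, zero variance, ...)."""


class ContractViolation(WMEntropyError, ValueError):
    """A precondition stated by the calling contract was violated."""


class PairingError(WMEntropyError, ValueError):
    """Tables that must align on subject/session do not; offenders are listed."""


class UndefinedCorrelationError(WMEntropyError, ValueError):
    """Correlation is undefined (too few pairs or zero variance)."""


class DegenerateFoldError(WMEntropyError, ValueError):
    """A cross-validation training fold lost one of the two classes."""


class UndefinedAUCError(WMEntropyError, ValueError):
    """ROC/AUC undefined because only one class is present."""


class DegenerateTargetError(WMEntropyError, ValueError):
    """Regression target has zero variance."""


class UndefinedChangeError(WMEntropyError, ValueError):
    """Change rate undefined because the two scores sum to zero."""


class PipelineError(WMEntropyError, RuntimeError):
    """A pipeline stage failed; the message names the stage."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"stage '{stage}' failed: {message}")
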