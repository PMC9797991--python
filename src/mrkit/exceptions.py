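"""Exception hierarchy for the MR pipeline.

Every error raised on a user-facing path derives from :class:`MRKitError`
so callers (and the CLI) can catch one base class.
"""


class MRKitError(Exception):
    """Base class for all mrkit errors."""


class ConfigurationError(MRKitError):
    """A configuration problem: missing column mapping, bad option value."""


class InputError(MRKitError):
    """Input data unusable: no valid rows, empty variant intersection."""


class DomainError(MRKitError, ValueError):
    """An argument outside the mathematical domain of an operation."""


class InsufficientInstrumentsError(MRKitError):
    """Too few instruments for the requested estimator."""


class GenerationError(MRKitError):
    """Synthetic-scenario parameters are infeasible."""


class PipelineError(MRKitError):
    """A pipeline stage failed; message carries stage and outcome label."""
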