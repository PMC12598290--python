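"""Exception hierarchy.

Everything derives from :class:`SeqBalanceError` (a ``ValueError``) so callers
can catch the whole family while still getting sane behaviour from generic
``except ValueError`` blocks.
"""


class SeqBalanceError(ValueError):
    """Base class for all seqbalance errors."""


class InvalidBudgetError(SeqBalanceError):
    """A cycle budget is internally inconsistent (e.g. index reads exceed cycles)."""


class InvalidParameterError(SeqBalanceError):
    """A planning parameter is out of its valid domain."""


class InvalidMeasurementError(SeqBalanceError):
    """A physical measurement (concentration, size) is out of its valid domain."""


class ConfigurationError(SeqBalanceError):
    """A required configuration value is missing or inconsistent."""


class InvalidRecordError(SeqBalanceError):
    """A per-sample QC record fails validation."""


class InvalidInputError(SeqBalanceError):
    """Generic invalid numeric input (non-positive totals, empty lists...)."""


class EmptyPlanError(SeqBalanceError):
    """Rebalancing excluded every sample; no plan can be produced."""


class IncompatibleTracksError(SeqBalanceError):
    """Depth tracks disagree on contig, bin size or extent."""


class DegenerateProfileError(SeqBalanceError):
    """An aggregate profile has zero global mean; accessibility is undefined."""


class InvalidPedigreeError(SeqBalanceError):
    """A pedigree graph is malformed (cycle, duplicate id...)."""
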