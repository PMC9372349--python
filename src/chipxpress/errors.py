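"""Exception hierarchy for the pipeline.

Every error raised deliberately by this package derives from
:class:`ChipXpressError`, so callers (and the CLI) can distinguish pipeline
failures from programming errors.
"""


class ChipXpressError(Exception):
    """Base class for all errors raised by this package."""


class ParseError(ChipXpressError):
    """A file could not be parsed; the message names the file and line."""


class ValidationError(ChipXpressError):
    """An input value violates a documented invariant."""


class ConfigurationError(ChipXpressError):
    """Inconsistent or incomplete configuration (e.g. sample without genotype)."""


class LookupMissingError(ChipXpressError):
    """A referenced record (peak, gene) is absent from the table it must be in."""


class InsufficientDataError(ChipXpressError):
    """Too few observations for the requested statistic."""


class CapacityError(ChipXpressError):
    """A simulated layout does not fit on the configured genome."""


class DegenerateNormalizationError(ChipXpressError):
    """A normalization denominator (e.g. a genotype mean CPM) is zero."""
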