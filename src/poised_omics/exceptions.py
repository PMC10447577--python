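"""Exception hierarchy for the pipeline.

All pipeline errors derive from :class:`PoisedOmicsError` so callers can
distinguish validation problems (bad inputs / configuration) from runtime
failures in a single ``except`` clause.
"""


class PoisedOmicsError(Exception):
    """Base class for all errors raised by this package."""


class FormatError(PoisedOmicsError):
    """A required column or structural element is missing from an input table."""


class ParseError(PoisedOmicsError):
    """A cell could not be parsed; the message names the row and column."""


class ConfigurationError(PoisedOmicsError):
    """A configuration value is out of its documented range."""


class RulerError(PoisedOmicsError):
    """The histone internal standard is unusable (e.g. zero signal in a sample)."""


class EmptyCategoryError(PoisedOmicsError):
    """A gene category is empty after intersection with the data."""


class IntegrationError(PoisedOmicsError):
    """The proteome/transcriptome join produced no genes."""
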