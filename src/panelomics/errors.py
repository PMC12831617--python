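"""Exception hierarchy shared across the package."""


class PanelomicsError(Exception):
    """Base class for all package-specific errors."""


class FormatError(PanelomicsError):
    """A delimited input file violates the expected layout."""


class ParseError(FormatError):
    """A cell could not be parsed as a number; names the row and column."""


class MissingnessError(PanelomicsError):
    """Fraction of missing cells exceeds the configured ceiling."""


class AlignmentError(PanelomicsError):
    """Sample sets of two tables cannot be aligned."""


class SpecError(PanelomicsError):
    """A synthetic-cohort specification is internally inconsistent."""


class InsufficientDataError(PanelomicsError):
    """Too few samples in a class for the requested statistic."""


class TrainingError(PanelomicsError):
    """Model training diverged or could not be completed."""
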