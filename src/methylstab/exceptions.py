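"""Exception hierarchy for methylstab.

All errors raised by the package derive from :class:`MethylStabError` so
callers can catch the package's failures with a single except clause.
"""


class MethylStabError(Exception):
    """Base class for all methylstab errors."""


class FormatError(MethylStabError):
    """A file violates the expected tabular format (duplicates, bad tokens)."""


class RangeError(MethylStabError):
    """A beta value lies outside [0, 1]; message names the offending cell."""


class AlignmentError(MethylStabError):
    """Detection p-value matrix does not align with its beta matrix."""


class SchemaError(MethylStabError):
    """A mandatory column is missing from an input table."""


class EmptyDesignError(MethylStabError):
    """No complete subject pairs remain after sample-sheet assembly."""


class InsufficientDataError(MethylStabError):
    """Too few observations for the requested statistic."""


class SpecError(MethylStabError):
    """Invalid synthetic-study specification."""


class ConfigError(MethylStabError):
    """Invalid or inconsistent pipeline configuration."""


class StageError(MethylStabError):
    """A pipeline stage failed; message names the stage."""
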