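"""Exception hierarchy.

All trialwise errors derive from :class:`TrialwiseError` so callers can
distinguish validation failures (bad parameters, malformed data or designs)
from genuine computation failures.
"""


class TrialwiseError(Exception):
    """Base class for all trialwise errors."""


class ParameterError(TrialwiseError, ValueError):
    """A function argument is outside its admissible range."""


class DataError(TrialwiseError, ValueError):
    """Input data violate a contract (unknown levels, mismatched grids...)."""


class DesignError(TrialwiseError, ValueError):
    """A design matrix is degenerate (constant or collinear columns, empty)."""


class FormatError(TrialwiseError, ValueError):
    """An on-disk bundle is inconsistent with its manifest."""
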