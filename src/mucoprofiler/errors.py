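"""Exception hierarchy.

Everything raised on bad input derives from :class:`MucoprofilerError` so callers
can catch pipeline failures without masking programming errors.
"""


class MucoprofilerError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(MucoprofilerError, ValueError):
    """A config object violates one of its invariants; the message names the field."""


class DetectionError(MucoprofilerError, ValueError):
    """Boundary detection failed (no tissue, no lumen, degenerate input)."""


class AmbiguityError(MucoprofilerError, ValueError):
    """Luminal orientation cannot be resolved automatically; manual override required."""


class ProfileError(MucoprofilerError, ValueError):
    """Distance-field / binning / normalization precondition violated."""


class AnalysisError(MucoprofilerError, ValueError):
    """Group-statistics precondition violated (empty cells, zero residual, off-grid)."""
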