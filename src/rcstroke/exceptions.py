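"""Exception hierarchy for rcstroke.

Every error raised deliberately by the package derives from
:class:`RCStrokeError`, so callers can catch one base class at pipeline
boundaries while tests can assert on the specific subclass.
"""


class RCStrokeError(Exception):
    """Base class for all rcstroke errors."""


class ConfigurationError(RCStrokeError):
    """Invalid simulation or pipeline configuration (e.g. sd <= 0)."""


class InputError(RCStrokeError):
    """Malformed tabular input: missing columns, missing values, duplicate ids."""


class FormatError(RCStrokeError):
    """Malformed image input: non-integer labels, non-binary mask, missing sidecar rows."""


class GridCompatibilityError(RCStrokeError):
    """Mask and atlas do not share shape, voxel dimensions or orientation."""


class CalibrationError(RCStrokeError):
    """Threshold calibration target is infeasible or degenerate."""


class GenerationError(RCStrokeError):
    """Synthetic image fixture could not be generated within bounded retries."""


class FitError(RCStrokeError):
    """Maximum-likelihood fit failed (non-convergence with diagnostics attached)."""

    def __init__(self, message, diagnostics=None):
        super().__init__(message)
        self.diagnostics = diagnostics or {}


class DegenerateOutcomeError(RCStrokeError):
    """Outcome column has fewer than two observed levels."""


class ComparisonError(RCStrokeError):
    """Likelihood-ratio comparison requested for non-nested models."""


class SubgroupError(RCStrokeError):
    """Requested subgroup (e.g. no rich-club involvement) is empty."""


class StabilityError(RCStrokeError):
    """Too many resampled fits were skipped for the stability report to be valid."""
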