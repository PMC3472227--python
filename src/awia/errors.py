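"""Exception hierarchy for the analysis pipeline.

Every stage raises a subclass of :class:`AwiaError` so callers (and the CLI)
can attribute a failure to its stage.
"""


class AwiaError(Exception):
    """Base class for all package errors."""


class FormatError(AwiaError):
    """Input file is structurally unusable (missing column, bad units)."""


class ValidationError(AwiaError):
    """Data violate a physical or structural invariant (A <= 0, non-monotone t)."""


class DetectionError(AwiaError):
    """A landmark (systolic foot) could not be located."""


class EstimationError(AwiaError):
    """Wave-speed estimation failed (degenerate loop, short search span)."""


class ClassificationError(AwiaError):
    """Wave peaks could not be classified (no forward lobe)."""


class ConfigError(AwiaError):
    """Invalid configuration or simulator specification."""
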