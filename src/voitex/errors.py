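"""Exception types shared across the pipeline stages."""


class VoitexError(Exception):
    """Base class for all package-specific errors."""


class GeometryError(VoitexError):
    """Invalid or inconsistent spatial configuration (overlaps, grid mismatch)."""


class MissingLabelError(VoitexError):
    """A requested label is absent from the label map."""


class ConfigError(VoitexError):
    """Invalid engine or pipeline configuration."""


class IncompleteScanError(VoitexError):
    """A scan is missing one or more of the expected ROI labels."""


class SelectionError(VoitexError):
    """Feature-selection stage failure (e.g. k exceeds available features)."""


class TrainingError(VoitexError):
    """Classifier training failure (degenerate input, non-convergence)."""


class SplitError(VoitexError):
    """Cross-validation stratification failure (a class is too small)."""
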