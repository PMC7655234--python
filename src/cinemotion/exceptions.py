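"""Exception types shared across the pipeline."""


class CinemotionError(Exception):
    """Base class for all package errors."""


class ConfigurationError(CinemotionError):
    """Invalid configuration value or file."""


class CoverageError(CinemotionError):
    """Control-point grid does not cover the image with cubic support."""


class SteadyStateError(CinemotionError):
    """No frame below the pre-steady-state intensity threshold."""


class TrackingError(CinemotionError):
    """Edge tracking failed (no line exceeded the minimum gradient)."""


class MaskError(CinemotionError):
    """A mask is empty where a non-empty one is required."""
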