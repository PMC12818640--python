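"""Exception hierarchy for the pipeline."""


class RPPGError(Exception):
    """Base class for all package errors."""


class InputError(RPPGError):
    """Malformed input data (wrong shape, mismatched lengths, ...)."""


class ConfigError(RPPGError):
    """Invalid parameter or configuration value."""


class DegenerateROIError(RPPGError):
    """ROI geometry produced an empty or zero-area pixel set."""


class ExtractionError(RPPGError):
    """Face never detected; no trace could be extracted."""


class LevelError(RPPGError):
    """Signal too short for the requested wavelet decomposition depth."""
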