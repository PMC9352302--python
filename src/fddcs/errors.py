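"""Exception types shared across the processing chain."""


class FDDCSError(Exception):
    """Base class for all package errors."""


class ConfigurationError(FDDCSError):
    """An instrument or simulation configuration is internally inconsistent."""


class AliasingError(ConfigurationError):
    """Temporal sampling too coarse for the requested dynamics (beat or decorrelation)."""


class MaskError(FDDCSError):
    """Mask geometry is out of bounds or masks overlap."""


class DegenerateInputError(FDDCSError):
    """Input carries no usable signal (e.g. an all-zero hologram stack)."""


class UndefinedSNRError(FDDCSError):
    """SNR is undefined for the given series (too short or zero spread)."""


class FitError(FDDCSError):
    """Model fit failed to converge."""
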