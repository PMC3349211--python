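"""Exception hierarchy shared across the pipeline stages."""


class McicaError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(McicaError):
    """Input data or metadata violates a documented invariant."""


class CalibrationError(McicaError):
    """Optical-density conversion produced non-finite values."""


class GenerationError(McicaError):
    """Phantom or mixture generation could not satisfy its constraints."""


class SamplingError(McicaError):
    """A patch/prototype sampling request exceeds the available pixels."""


class BorderError(McicaError):
    """A sampling window would overhang the image border."""


class ConvergenceError(McicaError):
    """Fixed-point ICA iteration did not converge within max_iter."""

    def __init__(self, message: str, n_iter: int | None = None):
        super().__init__(message)
        self.n_iter = n_iter


class RankError(McicaError):
    """Requested more components than the data rank supports."""


class ConfigError(McicaError):
    """Inconsistent classifier/analyzer configuration."""


class TrainingError(McicaError):
    """Network training diverged or received an unusable split."""


class GeometryError(McicaError):
    """Degenerate physical geometry (e.g. neighbourhood larger than image)."""
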