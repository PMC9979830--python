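"""Exception hierarchy shared across the package."""


class ChemurinError(Exception):
    """Base class for all package-specific errors."""


class SpectrumParseError(ChemurinError):
    """A spectra or manifest file could not be parsed; names the offending line."""


class SpectrumValidationError(ChemurinError):
    """A spectrum violates an invariant (grid order, NaN intensity, length)."""


class GridRangeError(ChemurinError):
    """A requested wavenumber grid falls outside a spectrum's native coverage."""


class ManifestError(ChemurinError):
    """Manifest is malformed or the spectrum/manifest join is not total."""


class ConvergenceError(ChemurinError):
    """Iterative baseline fitting failed to converge.

    Carries the last iterate so callers can inspect how far it got.
    """

    def __init__(self, message, corrected=None, baseline=None, iterations=None):
        super().__init__(message)
        self.corrected = corrected
        self.baseline = baseline
        self.iterations = iterations


class SingularScatterError(ChemurinError):
    """Within-class scatter is singular; advise retaining fewer components."""


class OrphanClassError(ChemurinError):
    """A cross-validation fold or screen definition leaves a class with too few samples."""


class UndefinedMetricError(ChemurinError):
    """A requested ratio metric has a zero denominator."""
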