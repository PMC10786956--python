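"""Exception hierarchy for the glottovib pipeline.

Every error raised by the package derives from :class:`GlottovibError` so
callers (and the CLI) can distinguish pipeline failures from programming
errors.  Validation problems (bad user input, malformed files) derive from
:class:`ValidationError`, which the CLI maps to exit code 3; configuration
problems map to exit code 2.
"""


class GlottovibError(Exception):
    """Base class for all pipeline errors."""


class ValidationError(GlottovibError):
    """Input data violates a documented contract."""


class ConfigError(GlottovibError):
    """Invalid or inconsistent pipeline configuration."""


class SamplingRateError(ValidationError):
    """Frame rate too low for the requested fundamental frequency."""


class DurationError(ValidationError):
    """Recording too short to contain the required number of cycles."""


class GeometryError(ValidationError):
    """Rendered glottis would not fit inside the image."""


class SeedingError(ValidationError):
    """Gap seed point does not fall inside a dark glottal-gap component."""


class EmptyStackError(ValidationError):
    """Frame stack contains no frames."""


class AperiodicityError(GlottovibError):
    """Glottal area waveform is not periodic enough to detect cycles.

    Carries the autocorrelation confidence that failed the threshold.
    """

    def __init__(self, confidence: float, threshold: float):
        self.confidence = float(confidence)
        self.threshold = float(threshold)
        super().__init__(
            f"aperiodic signal: autocorrelation confidence "
            f"{self.confidence:.3f} below threshold {self.threshold:.3f}"
        )


class InsufficientCyclesError(GlottovibError):
    """Fewer complete vibratory cycles than the analysis requires."""


class SilentGlottisError(GlottovibError):
    """Glottis never opens; area-based measures are undefined."""


class FormatError(ValidationError):
    """File does not conform to the documented on-disk format."""
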