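"""Exception hierarchy shared across the pipeline."""


class LysoposError(Exception):
    """Base class for all package errors."""


class ParameterError(LysoposError, ValueError):
    """A simulation or analysis parameter violates its stated constraint."""


class SegmentationError(LysoposError, RuntimeError):
    """Thresholding produced no usable foreground on the named channel."""

    def __init__(self, channel: str, message: str | None = None):
        self.channel = channel
        super().__init__(message or f"segmentation failed on channel {channel!r}")


class CentrosomeNotFoundError(LysoposError, RuntimeError):
    """The centrosome channel carries no localizable peak."""


class DegenerateCellError(LysoposError, RuntimeError):
    """A cell whose background-corrected total intensity is not positive."""


class EmptyGroupError(LysoposError, RuntimeError):
    """Every cell of an experimental group was dropped during profiling."""


class SampleSizeError(LysoposError, ValueError):
    """A test was requested on fewer observations than it is defined for."""


class DegenerateSampleError(LysoposError, RuntimeError):
    """Samples without the variation a test statistic requires.

    For the Brunner-Munzel test the attribute ``p_hat`` still carries the
    stochastic-superiority estimate (0 or 1 under complete tied separation).
    """

    def __init__(self, message: str, p_hat: float | None = None):
        self.p_hat = p_hat
        super().__init__(message)


class DegenerateStratificationError(LysoposError, RuntimeError):
    """Expression values carry no ordering information for a quantile cut."""


class UndefinedTestError(LysoposError, RuntimeError):
    """A survival comparison with no observed events."""
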