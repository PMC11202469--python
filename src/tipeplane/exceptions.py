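"""Exception types raised across the package."""


class TipeplaneError(Exception):
    """Base class for all errors raised by this package."""


class DegenerateSeriesError(TipeplaneError, ValueError):
    """The input series is constant (zero variance), so the Gaussian-CDF
    normalization and everything downstream are undefined."""


class SeriesTooShortError(TipeplaneError, ValueError):
    """The series is shorter than the minimum length the embedding needs."""

    def __init__(self, length: int, required: int, context: str = ""):
        self.length = length
        self.required = required
        msg = f"series of length {length} is too short: need at least {required} samples"
        if context:
            msg += f" ({context})"
        super().__init__(msg)


class SeriesParseError(TipeplaneError, ValueError):
    """A series file contained a line that could not be parsed as a number."""
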