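"""Exception hierarchy for csmat."""


class CsmatError(Exception):
    """Base class for all csmat errors."""


class FrameRangeError(CsmatError, ValueError):
    """A frame value lies outside the admissible voltage range."""


class FrameParseError(CsmatError, ValueError):
    """A frame or sample file could not be parsed."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


class AddressError(CsmatError, ValueError):
    """A sample address lies outside the sensor grid."""


class DuplicateAddressError(CsmatError, ValueError):
    """The same grid cell appears twice in one sample set."""


class RankDeficientSensingError(CsmatError, ValueError):
    """The sensing matrix has linearly dependent rows; regenerate the plan."""


class DegenerateGeometryError(CsmatError, ValueError):
    """Sample addresses are collinear; triangulation is impossible."""


class InsufficientValleysError(CsmatError, ValueError):
    """Fewer than two breathing valleys were found in an epoch."""


class ZeroVarianceError(CsmatError, ValueError):
    """Correlation is undefined for a constant series."""
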