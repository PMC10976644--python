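"""Exception hierarchy shared across the package."""


class SpinMPError(Exception):
    """Base class for all package errors."""


class InvalidInputError(SpinMPError):
    """Non-finite coordinates or otherwise malformed numeric input."""


class IncompatibleStructuresError(SpinMPError):
    """Two structures that cannot be superposed (atom count/element mismatch)."""


class ExtXYZParseError(SpinMPError):
    """Malformed extended-XYZ frame; carries the offending frame index."""

    def __init__(self, message: str, frame: int | None = None):
        super().__init__(f"frame {frame}: {message}" if frame is not None else message)
        self.frame = frame


class UnknownElementError(SpinMPError):
    """Atomic number outside the supported element table."""


class ConfigurationError(SpinMPError):
    """Invalid model / run configuration."""


class PairingError(SpinMPError):
    """HS/LS records that do not belong to the same configuration."""


class DataError(SpinMPError):
    """Dataset records missing required labels or annotations."""


class EmptyGridError(SpinMPError):
    """Frequency cutoff admits no wave vector."""


class SingularGeometryError(SpinMPError):
    """Coincident atoms make a pair potential undefined."""
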