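"""Exception hierarchy shared across the package."""


class WheelVaultError(Exception):
    """Base class for all package-specific errors."""


class ConfigError(WheelVaultError):
    """A configuration is internally inconsistent or infeasible."""


class FormatError(WheelVaultError):
    """A file does not conform to the expected on-disk format."""


class InputError(WheelVaultError):
    """An in-memory input violates a precondition."""


class EmptyMaskError(InputError):
    """A binary mask with no foreground pixels where one is required."""


class OrderingError(InputError):
    """Frame indices violate the required temporal ordering."""


class MissingKeypointError(InputError):
    """A keypoint set is incomplete; the performance must be discarded."""


class DegenerateGeometryError(InputError):
    """A zero-length limb vector makes a joint angle undefined."""


class SplitError(InputError):
    """A train/test split cannot be formed from the given records."""


class EventDetectionError(WheelVaultError):
    """Base class for key-frame detector failures."""

    def __init__(self, message: str, stage: str | None = None):
        super().__init__(message)
        self.stage = stage


class NoTakeoffError(EventDetectionError):
    pass


class NoContactError(EventDetectionError):
    pass


class NoThrustError(EventDetectionError):
    pass


class EventExtractionError(EventDetectionError):
    """Composite extraction failed; ``stage`` names the failing detector."""
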