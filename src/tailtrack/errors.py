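"""Exception hierarchy shared across the package."""


class TailtrackError(Exception):
    """Base class for all package-specific errors."""


class InvalidArgumentError(TailtrackError, ValueError):
    """An argument violates a documented precondition."""


class DegenerateInputError(TailtrackError, ValueError):
    """Input carries no usable signal (e.g. two constant volumes)."""


class InvalidMetadataError(TailtrackError, ValueError):
    """Volume metadata (voxel size) is missing or contradictory."""


class ConfigError(TailtrackError, ValueError):
    """A run-configuration field violates its constraint."""


class ResourceLimitError(TailtrackError, RuntimeError):
    """A configured resource budget (e.g. voxel count) would be exceeded."""
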