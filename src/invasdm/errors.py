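"""Exception hierarchy shared by all pipeline stages.

Exit-code mapping for the CLI: ConfigError -> 2, DataError -> 3,
NumericError -> 4 (anything else propagates as 1).
"""


class InvasdmError(Exception):
    """Base class for all package errors."""


class ConfigError(InvasdmError):
    """Invalid configuration or invalid argument values."""


class DataError(InvasdmError):
    """Input data violates a contract (empty, degenerate, misaligned...)."""


class NumericError(InvasdmError):
    """A numeric result is undefined for the given inputs."""


class CapacityError(DataError):
    """Fewer eligible cells/records than requested; carries the eligible count."""

    def __init__(self, message: str, eligible: int):
        super().__init__(message)
        self.eligible = eligible


class AlignmentError(DataError):
    """Grids with mismatched geometry were combined."""


class GateError(DataError):
    """No ensemble member passed the skill gate."""
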