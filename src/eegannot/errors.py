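"""Exception hierarchy for the eegannot package."""


class EegannotError(Exception):
    """Base class for all package-specific errors."""


class ConfigError(EegannotError, ValueError):
    """Invalid simulation / training / filter configuration."""


class FormatError(EegannotError, ValueError):
    """Unknown or malformed file format."""


class IntegrityError(EegannotError, ValueError):
    """File contents inconsistent with their header, or tables that do not line up."""


class ValidationError(EegannotError, ValueError):
    """Table row failed validation (carries the offending row number when known)."""

    def __init__(self, message: str, row: int | None = None):
        super().__init__(message if row is None else f"row {row}: {message}")
        self.row = row


class MontageError(EegannotError, KeyError):
    """Required channels missing from a recording."""

    def __init__(self, missing: list[str]):
        super().__init__(f"missing channels: {', '.join(missing)}")
        self.missing = list(missing)


class FilterDesignError(EegannotError, ValueError):
    """Impossible band-pass specification (e.g. cutoff at or above Nyquist)."""


class SignalLengthError(EegannotError, ValueError):
    """Signal too short for the requested operation."""


class NormalizationError(EegannotError, ValueError):
    """Degenerate (constant) input cannot be Z-scored."""


class TrainingError(EegannotError, RuntimeError):
    """Optimization failure (e.g. NaN loss), with fold/epoch context."""
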