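"""Exception hierarchy shared across the package."""


class ErgocalError(Exception):
    """Base class for all package-specific errors."""


class FormatError(ErgocalError):
    """A file does not conform to the declared dialect or schema."""


class DataError(ErgocalError):
    """A file parsed, but its content violates a data invariant."""


class DomainError(ErgocalError, ValueError):
    """An argument is outside the physical/physiological domain of an operation."""


class ConfigurationError(ErgocalError):
    """A required configuration item (equation, preset, schema field) is missing."""


class InfeasibleError(ErgocalError):
    """A prescription solver cannot satisfy its constraints (e.g. negative duration)."""
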