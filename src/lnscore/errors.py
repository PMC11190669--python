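"""Exception hierarchy shared across the package.

Every error raised on bad scientific input derives from :class:`LnscoreError`
so callers can distinguish domain problems from programming bugs.
"""


class LnscoreError(Exception):
    """Base class for all package-specific errors."""


class SchemaError(LnscoreError):
    """A required column or field is missing from an input table."""


class ValidationError(LnscoreError):
    """An input value violates a documented invariant."""


class DomainError(LnscoreError, ValueError):
    """A numeric argument is outside the mathematical domain of a formula."""


class DispatchError(LnscoreError):
    """The wrong age-specific formula was requested for a record."""


class InsufficientDataError(LnscoreError):
    """Too few usable measurements to compute the requested quantity."""


class IndeterminateError(LnscoreError):
    """No discriminating field is available, so no label can be assigned."""


class ConfigError(LnscoreError):
    """An analysis configuration is internally inconsistent."""
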