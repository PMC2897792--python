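"""Exception hierarchy.

All package-specific failures derive from :class:`ComorbidikitError` so that
callers (and the CLI, which maps them to exit code 2) can distinguish
validation problems from programming errors.
"""


class ComorbidikitError(Exception):
    """Base class for all comorbidikit errors."""


class ValidationError(ComorbidikitError):
    """Input rows or values violate the documented schema.

    ``diagnostics`` is a list of row-located messages; validation is total,
    so every rejected row appears here rather than being silently dropped.
    """

    def __init__(self, message, diagnostics=None):
        super().__init__(message)
        self.diagnostics = list(diagnostics or [])


class LinkageError(ValidationError):
    """An admission's patient_id has no demographics record."""

    def __init__(self, message, orphan_ids=()):
        super().__init__(message)
        self.orphan_ids = sorted(orphan_ids)


class ConfigError(ComorbidikitError):
    """A run or simulation configuration is invalid."""


class ReferenceDataError(ComorbidikitError):
    """A bundled or user-supplied reference table is malformed."""


class DataInconsistencyError(ComorbidikitError):
    """Claims and registry disagree in a way that cannot be reconciled."""


class DegenerateOutcomeError(ComorbidikitError):
    """The outcome vector has no events or no non-events."""


class UndefinedStatisticError(ComorbidikitError):
    """A statistic (e.g. the c-statistic) is undefined for this input."""


class ContractError(ComorbidikitError):
    """A caller violated an operation's precondition (e.g. non-nested models)."""
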