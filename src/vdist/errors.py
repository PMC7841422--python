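"""Exception and warning hierarchy.

All package errors derive from :class:`VdistError` so callers can catch one
base class; warnings derive from :class:`VdistWarning` so batch drivers can
record and count them (clipping, physical floors, exclusions).
"""


class VdistError(Exception):
    """Base class for all errors raised by this package."""


class DomainError(VdistError, ValueError):
    """An input is outside its physically meaningful domain (e.g. Hct >= 1)."""


class ValidationError(VdistError, ValueError):
    """A record violates a documented invariant (names the failing field/row)."""


class FormatError(VdistError, ValueError):
    """A table is structurally wrong (missing column, unreadable header)."""


class InputError(VdistError, ValueError):
    """A required input is missing for the requested operation."""


class ConfigError(VdistError, ValueError):
    """A run or simulation configuration is inconsistent."""


class ConsistencyError(VdistError, ValueError):
    """Two inputs that must agree do not (e.g. Kp vector missing a tissue)."""


class AnalyticalFailureError(VdistError, ValueError):
    """An assay readout cannot be interpreted (e.g. zero medium signal)."""


class VdistWarning(UserWarning):
    """Base class for package warnings."""


class ClipWarning(VdistWarning):
    """A predicted input was clipped to its assay limit."""


class FloorWarning(VdistWarning):
    """A derived quantity fell below its physical floor and was set to it."""


class ExclusionWarning(VdistWarning):
    """A compound was excluded from a method or report."""
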