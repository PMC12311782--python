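"""Exception hierarchy.

Every error raised on purpose by this package derives from :class:`DmsprofError`
so callers (and the CLI) can distinguish expected failure modes from bugs.
"""


class DmsprofError(Exception):
    """Base class for all dmsprof errors."""


class FormatError(DmsprofError):
    """A file does not parse as the documented dialect."""


class ValidationError(DmsprofError):
    """Parsed data violates a model invariant."""


class SelectionError(DmsprofError):
    """A selection names an unknown sample/reference/section."""


class InsufficientDataError(DmsprofError):
    """Too few unmasked positions for the requested statistic."""


class CardinalityError(DmsprofError):
    """A plot kind received the wrong number of selected rows."""


class FeasibilityError(DmsprofError):
    """A design request is provably or practically unsatisfiable."""


class UnavailableError(DmsprofError):
    """The requested quantity is not present in the input (e.g. no
    substitution breakdown in converted third-party data)."""


class ConfigurationError(DmsprofError):
    """The study lacks annotation required by the requested operation."""
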