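"""Exception hierarchy for promcat.

``PromcatError`` is the base for every error the library raises on purpose;
the CLI maps it to exit code 1 (user/data error) and everything else to
exit code 2 (internal error).
"""


class PromcatError(Exception):
    """Base class for all promcat errors."""


class InvalidInputError(PromcatError, ValueError):
    """A value supplied by the caller violates an operation's contract."""


class ConfigurationError(PromcatError):
    """A configuration object is incomplete or inconsistent."""


class CalibrationError(PromcatError):
    """Item calibration cannot proceed (e.g. unobserved interior category)."""


class AssessmentComplete(PromcatError):
    """Raised when item selection is requested but no items remain."""
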