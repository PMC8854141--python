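"""Exception hierarchy.

All package-specific failures derive from :class:`VocSenseError` so callers
can catch one base class; subclasses also derive from the matching builtin
(ValueError / RuntimeError) for idiomatic handling.
"""


class VocSenseError(Exception):
    """Base class for all vocsense errors."""


class ConfigError(VocSenseError, ValueError):
    """Invalid configuration; the message names the offending field."""


class FormatError(VocSenseError, ValueError):
    """Malformed on-disk table; the message carries row/column context."""


class AlignmentError(VocSenseError, ValueError):
    """Online and offline time spans do not intersect."""


class SelectionError(VocSenseError, ValueError):
    """Channel-selection step produced an empty or degenerate result."""


class TrainingError(VocSenseError, RuntimeError):
    """Network training could not make progress."""


class EvaluationError(VocSenseError, ValueError):
    """Model evaluation is impossible on the given data."""
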