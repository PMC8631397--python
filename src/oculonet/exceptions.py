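"""Exception hierarchy.

Argument/precondition violations raise :class:`ValueError` (or
:class:`TypeError`) directly; these classes cover failures that arise
*during* a computation on formally valid input.
"""


class OculonetError(Exception):
    """Base class for all package-specific errors."""


class ComputationError(OculonetError):
    """A statistic is undefined on the given data (e.g. zero variance)."""


class DetectionError(OculonetError):
    """Event detection cannot proceed (empty or all-invalid recording)."""


class SummaryError(OculonetError):
    """A subject summary cannot be formed; lists the missing components."""


class FixtureError(OculonetError):
    """A packaged fixture table is missing or corrupt."""
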