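"""Exception hierarchy shared across the package."""


class PocketspaceError(Exception):
    """Base class for all package-specific errors."""


class ParseError(PocketspaceError):
    """A structure file could not be parsed; the message names the offending file/line."""


class EmptyStructureError(PocketspaceError):
    """Parsed file contains no protein chain."""


class EmptyPocketError(PocketspaceError):
    """A ligand makes no contact with the protein; the ligand is skipped."""


class ConfigurationError(PocketspaceError):
    """Missing radii/parameters that the caller must supply."""


class SuperpositionError(PocketspaceError):
    """Rigid superposition is undefined (too few or degenerate points)."""


class AlignmentError(PocketspaceError):
    """Pocket alignment cannot be performed (e.g. pocket too small)."""


class CalibrationError(PocketspaceError):
    """A statistical model is missing or cannot be fitted."""


class DomainError(PocketspaceError):
    """An argument is outside the operation's domain (e.g. empty sequence)."""
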