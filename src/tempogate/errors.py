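"""Exception hierarchy shared across the package."""


class TempogateError(Exception):
    """Base class for all package-specific errors."""


class SpecValidationError(TempogateError, ValueError):
    """A generative design specification violates one of its invariants.

    The message always names the offending field.
    """


class ParameterError(TempogateError, ValueError):
    """An operation was called with parameters outside its contract."""


class FormatError(TempogateError, ValueError):
    """An on-disk epoch container is malformed; the message names the field."""


class VersionError(FormatError):
    """An on-disk container uses an unsupported schema version."""


class IncompleteDesignError(TempogateError, ValueError):
    """A repeated-measures table is missing a subject x cell combination."""


class EmptyCellError(TempogateError, ValueError):
    """A condition cell contains no trials."""
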