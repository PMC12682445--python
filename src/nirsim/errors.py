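"""Exception hierarchy.

All package errors derive from :class:`NirsimError` so callers can catch one
type.  Most also derive from ``ValueError`` for ergonomic use in scripts.
"""


class NirsimError(Exception):
    """Base class for all package errors."""


class InputError(NirsimError, ValueError):
    """Invalid input data (bad shapes, missing ids, invariant violations)."""


class FormatError(InputError):
    """Malformed on-disk file (bad header, ragged rows)."""


class ParseError(InputError):
    """A cell or token could not be parsed; message names row/column."""


class ParameterError(NirsimError, ValueError):
    """Invalid algorithm parameter (even SG window, bad grid options...)."""


class ConfigurationError(NirsimError, ValueError):
    """Invalid or inconsistent run configuration."""


class UndefinedValueError(NirsimError, ValueError):
    """A metric is mathematically undefined for the given input
    (constant vector to Pearson, zero vector to SAM)."""


class ConsistencyError(NirsimError, ValueError):
    """Internal bookkeeping mismatch (e.g. a pair batch not covering all
    sample pairs)."""
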