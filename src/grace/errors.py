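"""Exception hierarchy shared across the package.

Two user-facing failure classes are distinguished so the command line
interface can map them to distinct exit codes: problems with the *shape*
or *content* of an input (``ValidationError``) versus problems with the
data relative to what an analysis needs (``DataError``).
"""


class GraceError(Exception):
    """Base class for all errors raised by this package."""


class ValidationError(GraceError, ValueError):
    """An input violates a structural contract (duplicates, bad cells, ...)."""


class DataError(GraceError, ValueError):
    """The data are structurally valid but unusable for the requested analysis."""
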