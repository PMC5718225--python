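"""Exception hierarchy.

``FormatError`` covers unreadable or mis-typed files (exit code 2 in the
CLI), ``GridError`` covers mismatched or malformed grid geometry (exit
code 3).
"""


class DirqaError(Exception):
    """Base class for all package errors."""


class FormatError(DirqaError):
    """File missing, unparsable, or of the wrong pixel type / dimension."""


class GridError(DirqaError):
    """Grid headers malformed or incompatible between inputs."""
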