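"""Exception hierarchy.

Validation errors (bad parameters, malformed inputs, violated contracts) are
distinguished from runtime/IO failures so the command-line layer can map them
to distinct exit codes.
"""


class ReefMetricsError(Exception):
    """Base class for all package errors."""


class ValidationError(ReefMetricsError, ValueError):
    """A precondition or type invariant was violated by the caller."""


class RasterIOError(ReefMetricsError, IOError):
    """A raster file could not be read or written."""
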