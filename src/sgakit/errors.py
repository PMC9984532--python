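"""Exception hierarchy shared across the pipeline.

Validation failures (malformed inputs, broken invariants) and computation
failures (degenerate data that cannot be analysed) are kept distinct so
the command-line layer can map them to different exit codes.
"""


class SgakitError(Exception):
    """Base class for all errors raised by this package."""


class ValidationError(SgakitError):
    """An input file or in-memory object violates a structural invariant."""


class ComputationError(SgakitError):
    """Data are structurally valid but too degenerate to analyse."""
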