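"""Package exceptions.

``ValidationError`` covers malformed inputs and schema problems (CLI exit
code 2); ``ComputationError`` covers failures inside a numerical stage
(CLI exit code 3).
"""


class VfarchError(Exception):
    """Base class for package errors."""


class ValidationError(VfarchError):
    """Input, schema, or argument validation failure."""


class ComputationError(VfarchError):
    """A numerical stage failed (non-convergence, degenerate data, ...)."""
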