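"""Exception hierarchy shared across the package.

``ValidationError`` marks bad user input (missing files, malformed
annotations, out-of-range parameters) and maps to CLI exit code 2.
``ComputationError`` marks degenerate numerics (flat contour, singular
covariance) and maps to CLI exit code 3.
"""


class PipelineError(Exception):
    """Base class for all package errors."""


class ValidationError(PipelineError, ValueError):
    """Invalid input data or parameters."""


class ComputationError(PipelineError, RuntimeError):
    """A computation could not be carried out on otherwise valid input."""
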