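"""Error taxonomy shared across the pipeline.

The command-line layer maps these onto distinct exit codes, so stages can
fail with a diagnosis of *what kind* of problem occurred (bad
configuration, bad data, or a numerical failure during estimation).
"""


class DCGradientError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(DCGradientError):
    """A configuration object or file is invalid or inconsistent."""


class DataError(DCGradientError):
    """Input data violate a precondition (shape, value range, missingness)."""


class EstimationError(DCGradientError):
    """A numerical estimation step failed (rank deficiency, non-convergence)."""
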