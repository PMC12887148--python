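"""Exception hierarchy shared across the pipeline stages."""


class SsprofitError(Exception):
    """Base class for all package errors."""


class ConfigError(SsprofitError):
    """Invalid configuration value or combination."""


class DataError(SsprofitError):
    """Malformed or inconsistent input data."""


class StructuralError(SsprofitError):
    """Structural defect in a pedigree or relationship graph (e.g. a cycle)."""


class NumericalError(SsprofitError):
    """Numerical failure: singular matrix, diverging solver, non-PD covariance."""


class PipelineError(SsprofitError):
    """A pipeline stage failed; message is tagged with the stage name."""
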