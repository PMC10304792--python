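"""Exception hierarchy for heterores.

Every domain error raised by this package derives from :class:`HeteroresError`
so callers (and the CLI) can distinguish modelling problems from programming
errors.
"""


class HeteroresError(ValueError):
    """Base class for all heterores domain errors."""


class UnderDeterminedFitError(HeteroresError):
    """The data cannot identify both distribution parameters.

    Raised e.g. when inoculum-effect data contain fewer than two distinct
    inoculum sizes, or when a dose-response data set is all-surviving or
    all-dead (no information about the median).
    """


class ConvergenceError(HeteroresError):
    """The nonlinear fit failed to converge after all restarts."""


class BootstrapUnstableError(HeteroresError):
    """More than 20% of bootstrap resamples failed to fit."""


class DegenerateCorrelationError(HeteroresError):
    """Correlation requested on constant (zero-variance) input."""


class SimulationDesignError(HeteroresError):
    """The assay design cannot produce any usable observation."""


class SchemaError(HeteroresError):
    """A CSV file is missing a required column."""


class CsvParseError(HeteroresError):
    """A CSV cell could not be parsed as the expected numeric type."""
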