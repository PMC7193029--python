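"""Exception hierarchy.

``ConfigurationError`` covers invalid user inputs (simulation configs, CLI
arguments, malformed weight tables); ``EstimationError`` covers data-driven
failures of the estimators (no events in a stratum, degenerate mixture);
``DegenerateCohortError`` flags cohorts on which the pseudo-R2 is undefined
(fewer than three events, zero or negative generalized variance, no survival
plateau). Simulation-study drivers catch ``DegenerateCohortError`` and count
the affected replications instead of aborting.
"""


class SurvDeltaError(Exception):
    """Base class for all package errors."""


class ConfigurationError(SurvDeltaError, ValueError):
    """Invalid configuration or input."""


class EstimationError(SurvDeltaError, RuntimeError):
    """A nuisance-parameter estimate cannot be formed from the data."""


class DegenerateCohortError(EstimationError):
    """The pseudo-R2 is undefined on this cohort (too few events, det <= 0, ...)."""
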