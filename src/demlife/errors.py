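"""Exception hierarchy for the pipeline."""


class DemlifeError(Exception):
    """Base class for all package errors."""


class ConfigurationError(DemlifeError):
    """A configuration value is invalid; the message names the field."""


class InputFormatError(DemlifeError):
    """An input table has malformed or unrecognised rows."""


class WindowError(DemlifeError):
    """The claims panel does not cover the requested analysis window."""


class ConsistencyError(DemlifeError):
    """Internally inconsistent records (e.g. diagnosis after censoring)."""


class UndefinedRateError(DemlifeError):
    """A rate was requested for a cell with zero person-years."""


class DegenerateDataError(DemlifeError):
    """Data cannot identify the model (e.g. all-zero event counts)."""


class EstimationError(DemlifeError):
    """A model fit failed to converge; carries solver diagnostics."""

    def __init__(self, message, diagnostics=None):
        super().__init__(message)
        self.diagnostics = diagnostics


class KannistoFitError(EstimationError):
    """Old-age smoothing failed for a stratum."""


class UnstableStratumError(DemlifeError):
    """Too many bootstrap replicates failed for a stratum."""
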