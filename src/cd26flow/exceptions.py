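"""Exception hierarchy for cd26flow."""


class CD26FlowError(Exception):
    """Base class for all package errors."""


class FCSFormatError(CD26FlowError):
    """The file is not an FCS 3.0/3.1 list-mode file this package can read."""


class FCSIntegrityError(CD26FlowError):
    """Declared and actual file contents disagree (truncated / inconsistent)."""


class PanelError(CD26FlowError):
    """A required marker of the panel could not be mapped to a channel."""


class ParameterError(CD26FlowError):
    """An argument is outside its admissible domain."""


class ConfigurationError(CD26FlowError):
    """A simulation / pipeline configuration is internally infeasible."""


class InsufficientEventsError(CD26FlowError):
    """Too few events to run a density-based operation."""


class CalibrationError(CD26FlowError):
    """The CD26 positivity cutoff could not be calibrated on CD3+ lymphocytes."""


class ConsistencyError(CD26FlowError):
    """A derived quantity violates a structural invariant (e.g. gate nesting)."""


class PairingError(CD26FlowError):
    """A gating report and a clinical record do not belong to the same sample."""
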