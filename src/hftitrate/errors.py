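"""Exception hierarchy for the titration rules engine."""


class HFTitrateError(Exception):
    """Base class for all package errors."""


class RejectedSampleError(HFTitrateError, ValueError):
    """A telemetry sample failed validation (e.g. non-positive vital, no vitals)."""


class ContractViolationError(HFTitrateError, ValueError):
    """A caller violated an operation precondition (unsorted input, duplicates...)."""


class IdempotencyError(HFTitrateError, RuntimeError):
    """An event that must be handled exactly once was handled twice."""


class SafetyViolationError(HFTitrateError, RuntimeError):
    """An action would push a dose past the guideline maximum; never clamped silently."""


class ConfigurationError(HFTitrateError, ValueError):
    """Invalid configuration (unknown drug, bad distribution parameters...)."""
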