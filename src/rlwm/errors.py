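"""Exception types shared across the package."""


class RlwmError(Exception):
    """Base class for package errors."""


class ConfigError(RlwmError, ValueError):
    """Invalid configuration; the message names the offending field."""


class SequencingError(RlwmError, RuntimeError):
    """Stimulus-sequence constraints cannot be satisfied."""


class DataError(RlwmError, ValueError):
    """Malformed or inconsistent trial data."""


class SpecError(RlwmError, ValueError):
    """Infeasible synthetic-cohort specification."""
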