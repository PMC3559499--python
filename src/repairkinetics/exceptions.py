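"""Exception hierarchy."""


class RepairKineticsError(Exception):
    """Base class for errors raised by this package."""


class ValidationError(RepairKineticsError, ValueError):
    """Malformed input: bad state, table, config or argument."""


class UnderdeterminedError(ValidationError):
    """Data cannot constrain the requested fit (e.g. a single time point)."""
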