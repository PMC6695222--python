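"""Exception types shared across the package."""


class RiskPoolError(Exception):
    """Base class for all package errors."""


class ValidationError(RiskPoolError, ValueError):
    """An input (action, stock, log row) violates a game or schema rule."""


class ConfigError(RiskPoolError, ValueError):
    """A configuration object or file is internally inconsistent."""


class DegenerateDataError(RiskPoolError, ValueError):
    """A statistical routine received data it cannot meaningfully analyze
    (e.g. fewer than two observations per group)."""
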