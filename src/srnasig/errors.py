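"""Exception hierarchy; CLI maps ConfigurationError to exit 2, DataError to 3."""


class SrnasigError(Exception):
    """Base class for package errors."""


class ConfigurationError(SrnasigError, ValueError):
    """Invalid parameters or configuration."""


class DataError(SrnasigError, ValueError):
    """Malformed, inconsistent or degenerate input data."""


class SimulationError(DataError):
    """Simulation could not satisfy its constraints (e.g. locus placement)."""
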