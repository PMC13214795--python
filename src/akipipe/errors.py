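"""Exception hierarchy used across the pipeline."""


class AkipipeError(Exception):
    """Base class for all package errors."""


class ConfigError(AkipipeError):
    """Invalid configuration value; the message names the offending field."""


class DataError(AkipipeError):
    """Structurally invalid input data (duplicates, bad timestamps, non-positive weight)."""


class UnitError(DataError):
    """Contradictory units recorded for a single parameter."""


class DegenerateTableError(AkipipeError):
    """A contingency table with a zero expected count; the test statistic is undefined."""
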