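"""Exception hierarchy.

Exit-code mapping used by the CLI: ConfigError -> 2, IngestError -> 3,
DegenerateDataError / MatchingError -> 4.
"""


class MosaicError(Exception):
    """Base class for all package errors."""


class ConfigError(MosaicError):
    """Invalid configuration value (bad alpha, iteration count, paths...)."""


class IngestError(MosaicError):
    """Malformed or implausible input data; message names the offending row/column."""


class MatchingError(MosaicError):
    """Too few demographically matched controls for a patient."""


class DegenerateDataError(MosaicError):
    """Statistically degenerate input (zero spread, empty ROI, rank deficiency)."""
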