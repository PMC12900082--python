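"""Exception taxonomy shared across the package.

Exit-code mapping used by the CLI: ConfigurationError -> 2, DataError -> 3.
"""


class OpenSetHARError(Exception):
    """Base class for all package errors."""


class ConfigurationError(OpenSetHARError):
    """Invalid user-supplied configuration (bad parameter, missing class...)."""


class DataError(OpenSetHARError):
    """Malformed or missing input data (file, column, non-finite sample)."""


class CalibrationError(OpenSetHARError):
    """A scorer could not be calibrated on the provided training logits."""
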