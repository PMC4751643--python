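"""Exception hierarchy.

``ConfigError`` maps to CLI exit code 2, ``DataError`` to exit code 3.
"""


class CortiquantError(Exception):
    """Base class for all package errors."""


class ConfigError(CortiquantError):
    """Invalid configuration or parameter value."""


class DataError(CortiquantError):
    """Invalid or degenerate input data."""


class DegenerateHistogramError(DataError):
    """An image whose histogram cannot be split into two classes."""


class NoTissueError(DataError):
    """A tissue mask with no foreground pixels."""


class VocabularyError(DataError):
    """A categorical value outside its fixed vocabulary."""


class OvercrowdedError(ConfigError):
    """Requested synthetic cells cannot be placed inside the tissue region."""


class FitError(DataError):
    """Model fitting failed (e.g. singular design)."""
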