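"""Exception hierarchy for the broachtap toolkit.

Everything raised deliberately by the library derives from
:class:`BroachTapError`, so callers (and the CLI) can distinguish
validation problems from genuine bugs.
"""


class BroachTapError(Exception):
    """Base class for all broachtap errors."""


class AudioFormatError(BroachTapError):
    """A WAV file could not be read or has an unsupported encoding."""


class EmptyInputError(BroachTapError):
    """An input (recording, window, table) contains no usable data."""


class SchemaError(BroachTapError):
    """A tabular input is missing required columns or violates its contract."""


class ConfigError(BroachTapError):
    """A configuration value is out of its admissible range."""


class InsufficientDataError(BroachTapError):
    """Too few observations for the requested fit or statistic."""


class DegenerateInputError(BroachTapError):
    """Input is formally valid but carries no information (e.g. zero variance in x)."""


class EmptyReportError(BroachTapError):
    """An end-to-end analysis produced no blows; carries diagnostics."""

    def __init__(self, message: str, diagnostics: dict | None = None):
        super().__init__(message)
        self.diagnostics = diagnostics or {}
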