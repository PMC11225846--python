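"""Exception hierarchy shared across the pipeline stages."""


class HilipidError(Exception):
    """Base class for package errors."""


class ConfigError(HilipidError):
    """Invalid configuration (CLI exit code 2)."""


class DataError(HilipidError):
    """Invalid or inconsistent input data (CLI exit code 3)."""


class BandNotFoundError(DataError):
    """No chromatographic band found for a lipid class."""
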