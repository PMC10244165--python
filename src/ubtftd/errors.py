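"""Exception hierarchy shared across the package."""


class UbtftdError(Exception):
    """Base class for all package errors."""


class CoordinateError(UbtftdError):
    """A genomic or coding coordinate is out of range or inconsistent."""


class FrameError(UbtftdError):
    """A coding sequence length is not compatible with codon structure."""


class TDSpecError(UbtftdError):
    """A tandem-duplication specification is internally inconsistent."""


class ConfigError(UbtftdError):
    """A configuration value is missing, unknown or invalid."""


class ArchitectureError(UbtftdError):
    """A planted or inferred clonal architecture violates nesting rules."""
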