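"""Exception types shared across the package."""


class GuidemethError(Exception):
    """Base class for all package errors."""


class ConfigurationError(GuidemethError):
    """Invalid simulation or pipeline configuration."""


class DataError(GuidemethError):
    """Inconsistent methylation count data (e.g. M > N)."""


class ParseError(GuidemethError):
    """Malformed input file; message carries file and line number."""


class GenerationError(GuidemethError):
    """Synthetic data could not be generated under the requested constraints."""
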