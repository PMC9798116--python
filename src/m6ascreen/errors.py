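"""Exception hierarchy shared across the pipeline stages."""


class M6AScreenError(Exception):
    """Base class for all package-specific errors."""


class ParseError(M6AScreenError):
    """A file could not be parsed; message carries row/column coordinates."""


class ConfigError(M6AScreenError):
    """An invalid configuration value; message names the offending field."""


class NormalizationError(M6AScreenError):
    """Spike-in normalization cannot proceed (no spike-ins, zero median)."""


class MissingContrastError(M6AScreenError):
    """A gene is absent from a required contrast; message lists what is missing."""


class AssayError(M6AScreenError):
    """Invalid bench-assay input (non-finite Ct, bad ELISA calibration)."""
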