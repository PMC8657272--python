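"""Exception hierarchy shared across the package."""


class MiriscoreError(Exception):
    """Base class for all package-specific errors."""


class FormatError(MiriscoreError):
    """Malformed input file (bad columns, non-numeric values, duplicates)."""


class ConfigError(MiriscoreError):
    """Invalid configuration or inconsistent metadata (e.g. unmapped sample)."""


class NormalizationError(MiriscoreError):
    """Normalization cannot proceed (e.g. all-zero sample)."""


class UnitError(MiriscoreError):
    """Operation received an expression matrix in the wrong unit."""


class CoordinateError(MiriscoreError):
    """Transcript/genome coordinate arithmetic out of bounds."""


class LookupError_(MiriscoreError):
    """Requested feature absent from an annotation or table."""
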