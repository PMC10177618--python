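"""Exception taxonomy shared across the package."""


class PsmflowError(Exception):
    """Base class for all package errors."""


class ConfigurationError(PsmflowError):
    """Invalid or inconsistent generator/pipeline configuration."""


class FormatError(PsmflowError):
    """Malformed input file (cell table, summary table, label stack)."""


class DegenerateGeometryError(PsmflowError):
    """Geometric input too degenerate to process (coplanar points, ...)."""


class InsufficientDataError(PsmflowError):
    """Not enough observations for the requested statistic."""
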