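"""Exception hierarchy shared across the pipeline."""


class DmtaError(Exception):
    """Base class for all pipeline errors."""


class FormatError(DmtaError):
    """A file does not conform to the expected on-disk layout."""


class GridError(DmtaError):
    """Scattered points do not form a complete rectangular lattice."""


class ValidationError(DmtaError):
    """A table or surface violates a structural invariant."""


class ParseError(DmtaError):
    """A cell or field could not be parsed; message names row/column."""


class ParameterError(DmtaError, ValueError):
    """An operation was called with an out-of-range setting."""


class DataQualityError(DmtaError):
    """Input data too degraded to process (e.g. mostly voids)."""


class SequencingError(DmtaError):
    """Pipeline stages were run out of order (e.g. form removal on voids)."""
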