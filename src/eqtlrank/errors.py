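"""Exception hierarchy shared across the package."""


class EqtlRankError(Exception):
    """Base class for all package errors."""


class FormatError(EqtlRankError, ValueError):
    """A file does not have the expected columns / layout."""


class ParseError(EqtlRankError, ValueError):
    """A field could not be parsed (names the offending row)."""


class ValidationError(EqtlRankError, ValueError):
    """Values violate a documented invariant."""


class DataError(EqtlRankError, ValueError):
    """Inputs are structurally valid but unusable (e.g. no sample overlap)."""


class PipelineError(EqtlRankError, RuntimeError):
    """A pipeline stage failed; message names the stage."""
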