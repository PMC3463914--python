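"""Exception hierarchy for leafcoex.

All package-specific errors derive from :class:`LeafcoexError` so callers can
catch the whole family; the CLI maps them to a nonzero exit status.
"""


class LeafcoexError(Exception):
    """Base class for all leafcoex errors."""


class ExpressionFormatError(LeafcoexError):
    """A delimited expression table is malformed (header, cell values, ...)."""


class DimensionError(LeafcoexError):
    """An input has the wrong shape (fewer than two zones, length mismatch)."""


class DuplicateGeneError(LeafcoexError):
    """Duplicate gene-model rows where unique rows were required."""


class DuplicateConflictError(DuplicateGeneError):
    """Rows share a gene_id but disagree on RPKM values; refusing to merge."""


class GeneLookupError(LeafcoexError, KeyError):
    """A gene_id or zone label does not resolve in the given table."""

    def __str__(self) -> str:  # KeyError quotes its arg; keep the message plain
        return Exception.__str__(self)


class InputSetError(LeafcoexError):
    """Query/target gene sets are invalid (overlapping, unresolvable)."""


class ParameterError(LeafcoexError, ValueError):
    """A parameter value is outside its documented domain."""


class CalibrationError(LeafcoexError):
    """A synthetic profile with the requested correlation cannot be built."""


class PipelineError(LeafcoexError):
    """A pipeline stage failed; carries the stage name for diagnostics."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"stage '{stage}': {message}")
        self.stage = stage
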