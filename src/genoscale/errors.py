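"""Exception hierarchy for genoscale."""


class GenoscaleError(Exception):
    """Base class for all genoscale errors."""


class ScaleError(GenoscaleError):
    """Raised when an operation is asked to cross the boundary of the
    scale hierarchy (no coarser / no finer scale) or when a scale that
    the operation needs is not populated."""


class HierarchyError(GenoscaleError):
    """Raised when structure data violates a hard hierarchy precondition
    (as opposed to findings reported by :func:`validate_hierarchy`)."""


class GssFormatError(GenoscaleError):
    """Raised on malformed GSS input.  Carries the offending line number
    when one is known."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


class PdbFormatError(GenoscaleError):
    """Raised on malformed or unsupported PDB input/output."""


class SelectionError(GenoscaleError):
    """Raised on invalid selection operands (bad index, non-prefix
    lineage, unknown chromosome, wrong arity)."""


class SequenceDbError(GenoscaleError):
    """Raised when a sequence database cannot satisfy a retrieval."""


class NotConfiguredError(GenoscaleError):
    """Raised by declared-but-unconfigured backends (remote Ensembl)."""


class GenerationError(GenoscaleError):
    """Raised when the synthetic generator cannot satisfy its constraints
    (e.g. confinement too tight for the step length)."""
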