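"""Exception hierarchy shared across the package."""


class PedigreeError(Exception):
    """Base class for all pedinbreed errors."""


class ParseError(PedigreeError):
    """A pedigree file could not be parsed (reported with a line number)."""


class ValidationError(PedigreeError):
    """A pedigree violates a structural rule (duplicate id, self-parentage,
    missing parent record, infeasible simulation design, ...)."""


class CycleError(ValidationError):
    """The parentage graph contains a cycle; the message names a member."""


class ConsistencyError(PedigreeError):
    """An internal precondition was violated (e.g. an ancestor's Mendelian
    sampling variance was read before it was finalized)."""


class OracleSizeError(PedigreeError):
    """A dense oracle was requested for a pedigree above its size cap."""
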