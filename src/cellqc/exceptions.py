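"""Exception hierarchy."""


class CellQCError(Exception):
    """Base class for all cellqc errors."""


class ParseError(CellQCError):
    """A file could not be parsed; the message names the offending line."""


class ValidationError(CellQCError):
    """Parsed data violates a structural invariant."""


class SchemaError(CellQCError):
    """A table is missing required columns."""


class ModelIOError(CellQCError):
    """A serialized model file is truncated, corrupt, or has an
    incompatible schema version."""
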