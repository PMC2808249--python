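"""Exception hierarchy shared across the pipeline."""


class BathyruleError(Exception):
    """Base class for all package-specific errors."""


class SchemaError(BathyruleError):
    """The input file header lacks a mapped column."""


class EmptyTableError(BathyruleError):
    """No valid species records survived parsing."""


class DegenerateDataError(BathyruleError):
    """Input has zero variance (or too few points) where a fit needs spread."""
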