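"""Exception hierarchy shared across the pipeline.

Each subclass maps to a distinct CLI exit code (see :mod:`fireconn.cli`).
"""


class FireconnError(Exception):
    """Base class for all package-specific errors."""


class SchemaError(FireconnError):
    """An input table is missing a required column."""


class ParseError(FireconnError):
    """A cell could not be parsed; the message carries the row number."""


class ValidationError(FireconnError):
    """A record violates a domain invariant (e.g. group count > total)."""


class InfeasibleError(FireconnError):
    """A simulation request cannot be satisfied (e.g. site packing)."""


class DegenerateModelError(FireconnError):
    """A model cannot be fit (constant predictor, too few observations)."""
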