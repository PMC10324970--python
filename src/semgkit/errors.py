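"""Exception types shared across the toolkit."""


class SemgKitError(Exception):
    """Base class for semgkit errors."""


class FormatError(SemgKitError, ValueError):
    """A file on disk violates the expected CSV dialect."""


class StructureError(SemgKitError, ValueError):
    """Trials within a set are structurally inconsistent."""


class DegenerateInputError(SemgKitError, ValueError):
    """An input is degenerate for the requested operation (e.g. constant series)."""


class NumericalError(SemgKitError, ArithmeticError):
    """A linear-algebra step failed (singular / rank-deficient input)."""
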