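"""Exception hierarchy: validation failures vs. computation failures."""


class GazelexError(Exception):
    """Base class for all package errors."""


class FormatError(GazelexError):
    """An input file could not be parsed (bad delimiter, missing columns, bad row)."""


class ValidationError(GazelexError):
    """Parsed data violate a structural invariant (overlaps, orphans, bad spans)."""


class DesignError(ValidationError):
    """A manifest does not realize the experimental design (pair occurs != 2 times)."""


class UndefinedProportionError(GazelexError):
    """Looking proportion requested for a trial with zero on-display time."""


class ConvergenceError(GazelexError):
    """A model fit failed to converge; carries optimizer diagnostics."""

    def __init__(self, message: str, trace: object = None):
        super().__init__(message)
        self.trace = trace
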