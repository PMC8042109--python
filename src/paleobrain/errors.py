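"""Exception hierarchy used across the package."""


class PaleobrainError(Exception):
    """Base class for all package-specific errors."""


class NewickParseError(PaleobrainError):
    """Malformed Newick input; message names the character offset when known."""


class ValidationError(PaleobrainError):
    """Input violates a documented invariant (duplicate labels, negative edges, ...)."""


class ParameterError(PaleobrainError):
    """A model parameter lies outside its admissible range."""


class FitError(PaleobrainError):
    """A model fit failed (rank deficiency, non-convergence, ...)."""
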