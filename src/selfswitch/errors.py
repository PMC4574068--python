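"""Exception hierarchy shared across the package."""


class SelfswitchError(Exception):
    """Base class for all package-specific errors."""


class TreeFormatError(SelfswitchError):
    """Malformed newick/NEXUS input."""


class TreeValidationError(SelfswitchError):
    """Tree violates a structural invariant (rooting, ultrametricity, labels)."""


class ParameterError(SelfswitchError, ValueError):
    """Rate/parameter outside its admissible domain."""


class DataError(SelfswitchError):
    """Character/state table inconsistent with the tree or coding scheme."""


class ConvergenceError(SelfswitchError):
    """An optimizer or simulator failed to converge / satisfy its stopping rule."""
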