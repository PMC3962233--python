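"""Exception hierarchy shared across the package."""


class JamuplsError(Exception):
    """Base class for all package-specific errors."""


class FormatError(JamuplsError):
    """A table cell or file layout violates the expected format."""


class IdError(JamuplsError):
    """Duplicate or otherwise invalid row/column identifiers."""


class LabelError(JamuplsError):
    """An efficacy label outside the configured class set."""


class AlignmentError(JamuplsError):
    """Paired artifacts whose identifier axes do not line up."""


class ShapeError(JamuplsError):
    """Array dimensions incompatible with a fitted model."""


class ConfigError(JamuplsError):
    """An infeasible or inconsistent configuration."""


class ComponentError(JamuplsError):
    """Requested number of latent components is not extractable."""


class FitError(JamuplsError):
    """Degenerate input that makes a model fit undefined."""


class ConvergenceError(JamuplsError):
    """Iterative fit failed to converge within the iteration budget."""


class ScalingError(JamuplsError):
    """A rescaling that requires a positive eigenvalue hit a zero."""
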