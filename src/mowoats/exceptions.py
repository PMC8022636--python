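"""Exception hierarchy shared across the package."""


class MowoatsError(Exception):
    """Base class for all package-specific errors."""


class FormatError(MowoatsError, ValueError):
    """Malformed delimited-text input (ragged rows, bad header, ...)."""


class ParseError(FormatError):
    """A cell that should be numeric failed to parse."""


class UniquenessError(FormatError):
    """Duplicate gene identifier in an input matrix."""


class ShapeError(MowoatsError, ValueError):
    """Mismatched vector/matrix dimensions."""


class DomainError(MowoatsError, ValueError):
    """Argument outside the operation's domain (k < 2, n < k, non-finite...)."""


class DegenerateSolutionError(MowoatsError, ValueError):
    """Solution with coincident centroids: separation-based indices undefined."""


class SelectionError(MowoatsError, RuntimeError):
    """No elite-list member yields a valid (multi-cluster) labeling."""


class GenerationError(MowoatsError, RuntimeError):
    """Synthetic-data generation could not satisfy its constraints."""


class StateError(MowoatsError, RuntimeError):
    """Operation invoked on an object in an invalid state."""
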