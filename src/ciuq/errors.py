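"""Exception types shared across the package."""


class CiuqError(Exception):
    """Base class for package errors."""


class InvalidShapeError(CiuqError, ValueError):
    """Shape weights outside the plausible range, or a degenerate shape."""


class DomainError(CiuqError, ValueError):
    """Argument outside the mathematical domain of an operation."""


class IncompleteInsertionError(CiuqError, ValueError):
    """Requested insertion depth would leave a contact outside the cochlea."""


class BackendError(CiuqError, RuntimeError):
    """Numerical failure inside an activation backend."""
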