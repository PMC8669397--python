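"""Exception types shared across the package."""


class MuklockError(Exception):
    """Base class for all package-specific errors."""


class DataError(MuklockError):
    """Invalid or degenerate input data (bad alphabet, empty lane, ...)."""


class ConvergenceError(MuklockError):
    """A numerical routine failed to reach its convergence criterion."""
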