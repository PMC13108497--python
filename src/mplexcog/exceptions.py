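"""Exception hierarchy shared across the package."""


class MplexcogError(Exception):
    """Base class for all package-specific errors."""


class ConfigError(MplexcogError, ValueError):
    """Invalid configuration (unsatisfiable density, bad ranges, ...)."""


class FormatError(MplexcogError, ValueError):
    """Malformed on-disk input (non-square matrix, NaN, asymmetry, ...)."""


class DisconnectedGraphError(MplexcogError, ValueError):
    """A graph required to be connected is not.

    Carries the number of components and one representative node per
    component so the caller can report something actionable.
    """

    def __init__(self, n_components: int, representatives):
        self.n_components = int(n_components)
        self.representatives = list(representatives)
        super().__init__(
            f"graph is disconnected: {self.n_components} components "
            f"(representative nodes: {self.representatives})"
        )


class ConvergenceError(MplexcogError, RuntimeError):
    """An iterative solver failed to reach its tolerance."""

    def __init__(self, residual: float, tol: float):
        self.residual = float(residual)
        self.tol = float(tol)
        super().__init__(
            f"eigen-solver residual {residual:.3e} exceeds tolerance {tol:.3e}"
        )
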