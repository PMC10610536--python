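"""Exception hierarchy shared across the package."""


class DDIWalkError(Exception):
    """Base class for all package-specific errors."""


class ParseError(DDIWalkError):
    """A table on disk violated the expected dialect (names the offending line)."""


class ValidationError(DDIWalkError):
    """An in-memory record violated a domain invariant."""


class ChemistryError(DDIWalkError):
    """SMILES parsing or fingerprinting failed; carries the offending string(s)."""


class SeedError(DDIWalkError):
    """A drug's seed proteins have empty intersection with the network."""


class UndefinedScoreError(DDIWalkError):
    """An association score is undefined (target set absent from the network)."""


class ConvergenceError(DDIWalkError):
    """Random-walk iteration failed to reach the tolerance within max_iter."""

    def __init__(self, residual: float, max_iter: int):
        self.residual = residual
        self.max_iter = max_iter
        super().__init__(
            f"random walk did not converge within {max_iter} iterations "
            f"(final L1 residual {residual:.3e})"
        )
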