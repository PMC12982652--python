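"""Exception hierarchy for chain validation and estimation failures."""


class EntrochainError(Exception):
    """Base class for all package-specific errors."""


class NonSquareMatrixError(EntrochainError):
    """Transition matrix is not square."""


class NegativeEntryError(EntrochainError):
    """Transition matrix contains a negative entry."""


class AllZeroRowError(EntrochainError):
    """A transition-matrix row has no positive entry, so it cannot be normalized."""


class DimensionMismatchError(EntrochainError):
    """Vector/matrix dimensions or levels do not agree."""


class ReducibleChainError(EntrochainError):
    """The chain is not irreducible; the stationary distribution is not unique.

    Carries ``classes``: the strongly-communicating classes found.
    """

    def __init__(self, message, classes=None):
        super().__init__(message)
        self.classes = classes or []


class MixingCapReachedError(EntrochainError):
    """Matrix powering hit the iteration cap before reaching the TV threshold."""


class InsufficientDataError(EntrochainError):
    """Not enough observations (e.g. zero usable windows) for an estimate.

    Carries ``macro`` and ``T`` context when raised from windowed estimation.
    """

    def __init__(self, message, macro=None, T=None):
        super().__init__(message)
        self.macro = macro
        self.T = T


class FixtureIntegrityError(EntrochainError):
    """Packaged data file failed its checksum."""


class MatrixParseError(EntrochainError):
    """Delimited matrix file is malformed; message carries row/column context."""
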