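"""Exception hierarchy used across the package."""


class FearextError(Exception):
    """Base class for all package-specific errors."""


class ConstraintInfeasibleError(FearextError):
    """A pseudo-randomization constraint cannot be satisfied."""


class InsufficientDataError(FearextError):
    """Too few usable observations for the requested computation."""


class MissingCellError(FearextError):
    """A design cell has no usable trials for a subject."""


class RankDeficiencyError(FearextError):
    """A regression design matrix is rank deficient.

    Carries the names of the offending columns in ``columns``.
    """

    def __init__(self, message: str, columns=()):
        super().__init__(message)
        self.columns = tuple(columns)
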