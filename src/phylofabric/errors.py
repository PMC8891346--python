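"""Exception types shared across the package."""


class PhyloFabricError(Exception):
    """Base class for all package errors."""


class NewickFormatError(PhyloFabricError, ValueError):
    """Raised when a Newick string cannot be parsed.

    The message includes the parser's report of the offending position.
    """


class MissingBranchLengthError(NewickFormatError):
    """Raised when a non-root edge carries no branch length."""


class TraitTableError(PhyloFabricError, ValueError):
    """Raised for malformed trait tables or tree/table binding failures."""


class EffectLocationError(PhyloFabricError, ValueError):
    """Raised when an effect references a branch or node not in the tree."""


class DegenerateCovarianceError(PhyloFabricError, ValueError):
    """Raised when the tip covariance matrix is singular or not PSD.

    Attributes
    ----------
    tips : list of str
        Labels of the tips implicated in the degeneracy (e.g. tips joined
        by zero-length paths), when identifiable.
    """

    def __init__(self, message, tips=None):
        super().__init__(message)
        self.tips = list(tips) if tips else []
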