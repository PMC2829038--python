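"""Exception hierarchy for sprpath.

Every error raised on user input derives from :class:`SprPathError` so callers
(and the CLI) can distinguish bad input from genuine bugs.
"""


class SprPathError(Exception):
    """Base class for all sprpath errors."""


class NewickError(SprPathError):
    """The Newick text could not be parsed."""


class NotBinaryError(SprPathError):
    """The tree contains a multifurcation or a unifurcation.

    The rooted SPR distance is defined for binary trees only; silently
    resolving polytomies would change the distance, so they are rejected.
    """


class DuplicateLabelError(SprPathError):
    """Two leaves of one tree carry the same label."""


class LeafSetMismatchError(SprPathError):
    """The two trees are not on the same taxon set."""


class InvalidMoveError(SprPathError):
    """An SPR move refers to edges that do not exist or violates the
    prune/regraft constraints (prune edge incident to the root handle,
    regraft edge inside the pruned component, or an identity-recreating
    regraft)."""


class ReductionError(SprPathError):
    """A reduction operation was called on inputs it is not defined for
    (e.g. cluster finding on identical trees)."""


class ExpansionError(SprPathError):
    """A collapsed-leaf label has no matching collapse record."""


class SimulationError(SprPathError):
    """The simulator cannot satisfy the request (e.g. not enough disjoint
    subtrees for the requested number of independent SPRs)."""
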