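"""Exception hierarchy."""


class ExprMapError(Exception):
    """Base class for all errors raised by this package."""


class FormatError(ExprMapError):
    """An input file violates its expected format or a container invariant."""


class IncomparableGeneError(ExprMapError):
    """A gene's profile cannot be compared to any map node.

    Raised when every node similarity is the incomparable sentinel, e.g. a
    profile with fewer observed values than ``min_overlap`` or with zero
    variance over every overlap.
    """

    def __init__(self, gene_id: str):
        self.gene_id = gene_id
        super().__init__(
            f"gene {gene_id!r} is incomparable to every map node "
            "(too few observed values or zero variance over the overlap)"
        )
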