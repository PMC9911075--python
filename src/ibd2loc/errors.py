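"""Exception hierarchy.

All errors raised by the library derive from :class:`Ibd2locError` so callers
can catch everything in one clause.  The CLI maps :class:`PedigreeError` and
:class:`InbredPairError` to exit code 2 (validation) and
:class:`UnsupportedFounderInbreedingError` to exit code 3 (a configuration the
two-locus theory does not cover).
"""


class Ibd2locError(ValueError):
    """Base class for all library errors."""


class PedigreeError(Ibd2locError):
    """Malformed pedigree structure or invalid operation on a pedigree."""


class InbredPairError(Ibd2locError):
    """An IBD-coefficient (kappa) operation was requested for an inbred individual."""


class UnsupportedFounderInbreedingError(Ibd2locError):
    """Founder inbreeding configuration outside the supported set.

    Partially inbred founders (0 < f < 1) make joint two-locus IBD
    probabilities ill-defined, and a completely inbred founder cannot be
    given parents by pedigree extension.
    """
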