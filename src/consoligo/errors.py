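"""Exception hierarchy.

Every error raised on user input derives from :class:`ConsoligoError` so the
CLI can map them onto exit statuses (input errors exit 1, parameter/usage
errors exit 2).
"""


class ConsoligoError(Exception):
    """Base class for all errors raised on bad input or bad parameters."""


class EmptyInputError(ConsoligoError):
    """The FASTA file contained no records."""


class AlignmentShapeError(ConsoligoError):
    """Records in the alignment do not all share the same length."""


class AlphabetError(ConsoligoError):
    """A sequence contains a character outside the IUPAC nucleotide alphabet."""


class AllGapColumnError(ConsoligoError):
    """An alignment column consists of gap characters only."""


class ParameterError(ConsoligoError):
    """Search parameters are inconsistent with each other or with the input."""
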