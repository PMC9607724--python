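"""Exception hierarchy.

All package-specific failures derive from :class:`BcrCoherenceError` so
callers can catch one base class at pipeline boundaries.
"""


class BcrCoherenceError(Exception):
    """Base class for all errors raised by this package."""


class MissingReference(BcrCoherenceError):
    """A germline reference file was empty or absent."""


class DuplicateGene(BcrCoherenceError):
    """The same (gene, allele) appeared more than once in a reference."""


class MalformedHeader(BcrCoherenceError):
    """A FASTA header could not be parsed as an IMGT-style gene*allele name."""


class MalformedName(BcrCoherenceError):
    """A gene name is not a recognizable immunoglobulin gene symbol."""


class MissingColumn(BcrCoherenceError):
    """A required column is absent from a tabular input."""


class InconsistentDonor(BcrCoherenceError):
    """The same cell appears with conflicting donor assignments."""


class NoReferenceForGene(BcrCoherenceError):
    """A gene referenced by an annotation is missing from the germline set."""


class LengthMismatch(BcrCoherenceError):
    """Positional identity was requested for sequences of unequal length."""


class EmptyPairSet(BcrCoherenceError):
    """A coherence statistic was requested over zero eligible pairs."""


class NoCandidates(BcrCoherenceError):
    """No reference concatenation could be built for a junction."""


class ConfigurationError(BcrCoherenceError):
    """A pipeline configuration is invalid; the message names the field."""
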