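"""Exception hierarchy for specdelim.

Every error raised by the library derives from :class:`SpecdelimError` so
callers (and the CLI) can trap pipeline failures uniformly.
"""


class SpecdelimError(Exception):
    """Base class for all specdelim errors."""


class UnalignedInputError(SpecdelimError):
    """Sequences in one locus differ in length (unaligned input)."""


class DuplicateSpecimenError(SpecdelimError):
    """A specimen identifier occurs more than once in an alignment."""


class NoSequencesError(SpecdelimError):
    """An input file contained no sequence records."""


class InvalidCharacterError(SpecdelimError):
    """A sequence contains characters outside A/C/G/T/-/N."""


class NoComparableSitesError(SpecdelimError):
    """Complete deletion removed every alignment column."""


class IncomparablePairError(SpecdelimError):
    """A sequence pair shares no comparable (ungapped, non-N) site."""


class EmptyGroupError(SpecdelimError):
    """A group in a grouping scheme has no members in the distance matrix."""


class NoMolecularVariationError(SpecdelimError):
    """All sequences identical: AMOVA variance components are undefined."""


class InvalidHierarchyError(SpecdelimError):
    """Candidate partitions are not nested coarse-to-fine."""


class NoCandidatesError(SpecdelimError):
    """An operation requiring candidates received an empty set."""


class NothingToCompareError(SpecdelimError):
    """Barcoding-gap analysis needs at least two lineages with distances."""


class NoOverlapError(SpecdelimError):
    """Overlap fraction requested but the intra/inter sets are disjoint."""


class ThetaUndefinedError(SpecdelimError):
    """Nucleotide diversity is so high that theta = pi/(1-4*pi/3) diverges."""


class InsufficientSampleError(SpecdelimError):
    """The zero-distance fallback for pi requires at least two specimens."""


class SaturationError(SpecdelimError):
    """Simulator configuration implies expected distances beyond saturation."""


class InconsistentInputsError(SpecdelimError):
    """Reports passed to the concordance step refer to different hypotheses."""


class UnassignableError(SpecdelimError):
    """A specimen is absent from every distance matrix and cannot be placed."""
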