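"""Exception hierarchy.

Every validation failure raises a distinct subclass of :class:`GeotypekitError`
so callers (and the CLI) can map failures to exit codes without string matching.
"""


class GeotypekitError(Exception):
    """Base class for all geotypekit errors."""


class ParseError(GeotypekitError):
    """A file could not be parsed; the message names the offending line."""


class EmptyInputError(GeotypekitError):
    """An input file or record collection was empty where data is required."""


class IncompatibleKmerSetsError(GeotypekitError):
    """Two k-mer sets with different k or canonical mode were compared."""


class UndefinedSimilarityError(GeotypekitError):
    """Similarity requested for an empty k-mer set."""


class LocusNotFoundError(GeotypekitError):
    """No primer pairing for a locus was found in a genome."""


class AmbiguousAmpliconError(GeotypekitError):
    """More than one non-overlapping valid primer pairing was found."""

    def __init__(self, locus, candidates):
        self.locus = locus
        self.candidates = candidates
        super().__init__(
            f"{locus}: {len(candidates)} non-overlapping amplicon candidates: "
            + ", ".join(f"{c.scaffold_id}:{c.start}-{c.end}({c.strand})" for c in candidates)
        )


class TruncatedAmpliconError(GeotypekitError):
    """Amplicon shorter than its trim specification."""


class UncallableAlleleError(GeotypekitError):
    """Allele sequence contains ambiguous bases and cannot be called."""


class AlignmentRequiredError(GeotypekitError):
    """Sequence length differs from the allele database; alignment needed."""


class IncompleteProfileError(GeotypekitError):
    """An allelic profile with missing alleles where a complete one is required."""


class AlignmentLengthError(GeotypekitError):
    """Sequences in an alignment have unequal lengths."""


class CodonError(GeotypekitError):
    """Internal stop codon or frame problem; the message names the position."""


class IncompleteMatrixError(GeotypekitError):
    """Haplotype matrix contains missing entries."""


class DegeneratePopulationError(GeotypekitError):
    """All loci monomorphic: expected mismatch variance is zero."""


class InsufficientTaxaError(GeotypekitError):
    """Too few sequences for the requested test."""


class MatrixValidationError(GeotypekitError):
    """Distance/similarity matrix failed symmetry or diagonal checks."""


class FixtureError(GeotypekitError):
    """Packaged fixture failed its pinned checksum or invariants."""


class ConfigError(GeotypekitError):
    """Simulation or run configuration is invalid."""
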