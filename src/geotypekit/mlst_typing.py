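"""In-silico six-locus MLST typing.

The typing path mirrors the laboratory workflow: each locus is recovered
from a draft assembly by locating its PCR primer pair (in silico, with a
small mismatch tolerance), the amplicon is trimmed to a fixed in-frame
region, and the trimmed sequence is looked up in a per-locus allele
database.  Novel sequences are appended and numbered in order of discovery
(ALA1-1, ALA1-2, ...); each unique six-number combination is a sequence
type (ST), likewise numbered in order of first observation.

Allele identity is exact string equality of the trimmed region — a single
SNP creates a new allele.  Coordinates are 0-based half-open on the forward
strand of the scaffold; amplicon sequences are reported 5'->3' on the locus
(coding) strand and INCLUDE both primer annealing sites.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .errors import (
    AlignmentRequiredError,
    AmbiguousAmpliconError,
    EmptyInputError,
    IncompleteProfileError,
    LocusNotFoundError,
    TruncatedAmpliconError,
    UncallableAlleleError,
)
from .io_formats import LOCUS_ORDER, PrimerPair
from .linkage_stats import MISSING, HaplotypeMatrix

_COMP = str.maketrans("ACGTRYKMBVDHNacgtrykmbvdhn", "TGCAYRMKVBHDNtgcayrmkvbhdn")


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


@dataclass(frozen=True)
class Amplicon:
    locus: str
    sequence: str  # 5'->3' on the locus strand, primers included
    scaffold_id: str
    start: int  # 0-based half-open, forward strand of the scaffold
    end: int
    strand: str  # "+" or "-"


def _encode(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode("ascii"), dtype=np.uint8)


def _find_primer(seq_arr: np.ndarray, primer: str, max_mismatches: int,
                 protect_3prime: int = 3) -> list[int]:
    """Start positions where ``primer`` matches with <= max_mismatches,
    none of them within the primer's 3'-terminal ``protect_3prime`` bases.

    The primer is given 5'->3' as it would anneal to this strand's
    sequence, i.e. already reverse-complemented by the caller when needed.
    """
    p = _encode(primer)
    lp = len(p)
    n = len(seq_arr)
    if n < lp:
        return []
    win = np.lib.stride_tricks.sliding_window_view(seq_arr, lp)
    mism = win != p
    total = mism.sum(axis=1)
    tail = mism[:, lp - protect_3prime :].any(axis=1)
    hits = np.flatnonzero((total <= max_mismatches) & ~tail)
    return [int(h) for h in hits]


def find_amplicon(
    records: list[tuple[str, str]],
    primer: PrimerPair,
    max_mismatches: int = 2,
    size_tolerance: float = 0.2,
) -> Amplicon:
    """Locate the primer pair on either strand and extract the amplicon.

    The forward primer and the reverse complement of the reverse primer
    must pair within ``locus_size * (1 +/- size_tolerance)``; the nearest
    valid pairing is taken.  No hit raises :class:`LocusNotFoundError`;
    more than one non-overlapping valid pairing raises
    :class:`AmbiguousAmpliconError` listing all of them.
    """
    if not records:
        raise EmptyInputError("no scaffolds to search")
    lo = int(round(primer.locus_size * (1 - size_tolerance)))
    hi = int(round(primer.locus_size * (1 + size_tolerance)))
    fwd = primer.forward
    rev_rc = revcomp(primer.reverse)  # as read on the locus strand
    candidates: list[Amplicon] = []

    for rid, seq in records:
        seq = seq.upper()
        arr = _encode(seq)
        # locus on the forward strand of this scaffold
        f_hits = _find_primer(arr, fwd, max_mismatches)
        r_hits = _find_primer(arr, rev_rc, max_mismatches)
        for fs in f_hits:
            ends = [rs + len(rev_rc) for rs in r_hits if lo <= rs + len(rev_rc) - fs <= hi]
            if ends:
                end = min(ends)  # nearest valid pairing
                candidates.append(Amplicon(primer.locus, seq[fs:end], rid, fs, end, "+"))
        # locus on the reverse strand: search the reverse complement
        rc = revcomp(seq)
        rc_arr = _encode(rc)
        f_hits = _find_primer(rc_arr, fwd, max_mismatches)
        r_hits = _find_primer(rc_arr, rev_rc, max_mismatches)
        for fs in f_hits:
            ends = [rs + len(rev_rc) for rs in r_hits if lo <= rs + len(rev_rc) - fs <= hi]
            if ends:
                end = min(ends)
                n = len(seq)
                candidates.append(
                    Amplicon(primer.locus, rc[fs:end], rid, n - end, n - fs, "-")
                )

    if not candidates:
        raise LocusNotFoundError(f"{primer.locus}: no primer pairing found")
    # collapse overlapping candidates on the same scaffold (keep the first)
    kept: list[Amplicon] = []
    for c in sorted(candidates, key=lambda a: (a.scaffold_id, a.start, a.end)):
        if any(
            k.scaffold_id == c.scaffold_id and c.start < k.end and k.start < c.end
            for k in kept
        ):
            continue
        kept.append(c)
    if len(kept) > 1:
        raise AmbiguousAmpliconError(primer.locus, kept)
    return kept[0]


@dataclass(frozen=True)
class TrimSpec:
    """In-frame trim: start offset and a codon-multiple length."""

    offset: int = 0
    length: int = 0  # 0 means "largest codon multiple of the remainder"

    def __post_init__(self):
        if self.offset < 0 or self.length < 0 or self.length % 3:
            raise ValueError("offset must be >= 0 and length a multiple of 3")


def default_trim_spec(locus_size: int) -> TrimSpec:
    """Offset 0, length = largest codon multiple of the expected size."""
    return TrimSpec(0, locus_size - locus_size % 3)


def trim_in_frame(amplicon_seq: str, spec: TrimSpec) -> str:
    """Cut the fixed in-frame region all strains of a locus share."""
    length = spec.length or (len(amplicon_seq) - spec.offset) // 3 * 3
    if spec.offset + length > len(amplicon_seq):
        raise TruncatedAmpliconError(
            f"amplicon of {len(amplicon_seq)} bp shorter than trim "
            f"{spec.offset}+{length}"
        )
    return amplicon_seq[spec.offset : spec.offset + length]


class AlleleDatabase:
    """Per-locus numbered allele sequences, numbered in order of discovery."""

    def __init__(self, locus: str, trim_spec: Optional[TrimSpec] = None):
        self.locus = locus
        self.trim_spec = trim_spec
        self.alleles: list[tuple[int, str]] = []
        self._index: dict[str, int] = {}

    def __len__(self) -> int:
        return len(self.alleles)

    @property
    def length(self) -> Optional[int]:
        return len(self.alleles[0][1]) if self.alleles else None

    def assign_allele(self, sequence: str) -> int:
        """Exact-match lookup; novel sequences get number max + 1.

        The database mutates only on novelty, so resubmitting a known
        sequence is idempotent.
        """
        seq = sequence.upper()
        if set(seq) - set("ACGT"):
            raise UncallableAlleleError(
                f"{self.locus}: ambiguous bases in allele sequence"
            )
        if self.length is not None and len(seq) != self.length:
            raise AlignmentRequiredError(
                f"{self.locus}: sequence length {len(seq)} != database length "
                f"{self.length}"
            )
        if seq in self._index:
            return self._index[seq]
        number = len(self.alleles) + 1
        self.alleles.append((number, seq))
        self._index[seq] = number
        return number

    def to_fasta_records(self) -> list[tuple[str, str]]:
        return [(f"{self.locus}_{n}", seq) for n, seq in self.alleles]

    @classmethod
    def from_fasta_records(cls, locus: str, records) -> "AlleleDatabase":
        db = cls(locus)
        for rid, seq in records:
            got = db.assign_allele(seq)
            expect = int(str(rid).rsplit("_", 1)[-1])
            if got != expect:
                raise ValueError(f"{locus}: allele numbering gap or duplicate at {rid}")
        return db


@dataclass(frozen=True)
class AllelicProfile:
    strain_id: str
    alleles: tuple[int, ...]  # locus order ALA1, CDC19, SAPT4, GLN4, PGI1, PGM2

    def is_complete(self) -> bool:
        return all(a is not None and a != MISSING for a in self.alleles)


class STRegistry:
    """Unique allele-number combination -> sequence type, in discovery order."""

    def __init__(self):
        self._index: dict[tuple[int, ...], int] = {}

    def __len__(self) -> int:
        return len(self._index)

    def assign_st(self, profile: AllelicProfile) -> int:
        if not profile.is_complete():
            raise IncompleteProfileError(
                f"{profile.strain_id}: profile has missing alleles"
            )
        key = tuple(int(a) for a in profile.alleles)
        if key not in self._index:
            self._index[key] = len(self._index) + 1
        return self._index[key]

    @property
    def mapping(self) -> dict[tuple[int, ...], int]:
        return dict(self._index)


def assign_st(profile: AllelicProfile, registry: STRegistry) -> int:
    return registry.assign_st(profile)


def type_matrix(matrix: HaplotypeMatrix) -> tuple[list[int], STRegistry]:
    """Assign STs to every row of an allelic-profile matrix, in row order."""
    registry = STRegistry()
    sts = [
        registry.assign_st(AllelicProfile(sid, tuple(int(a) for a in row)))
        for sid, row in zip(matrix.strain_ids, matrix.alleles)
    ]
    return sts, registry


def type_genome(
    records: list[tuple[str, str]],
    primers: Sequence[PrimerPair],
    databases: dict[str, AlleleDatabase],
    registry: STRegistry,
    strain_id: str = "",
    trim_specs: Optional[dict[str, TrimSpec]] = None,
    max_mismatches: int = 2,
    size_tolerance: float = 0.2,
) -> tuple[AllelicProfile, int, dict[str, Amplicon]]:
    """Full in-silico typing of one assembly.

    Recovers every locus in :data:`LOCUS_ORDER` with the matching primer
    pair, trims in frame, calls alleles against (and extends) the given
    databases, and assigns the ST.
    """
    by_locus = {p.locus: p for p in primers}
    trim_specs = trim_specs or {}
    numbers, amplicons = [], {}
    for locus in LOCUS_ORDER:
        primer = by_locus[locus]
        amp = find_amplicon(records, primer, max_mismatches, size_tolerance)
        spec = trim_specs.get(locus) or databases[locus].trim_spec or default_trim_spec(
            primer.locus_size
        )
        trimmed = trim_in_frame(amp.sequence, spec)
        numbers.append(databases[locus].assign_allele(trimmed))
        amplicons[locus] = amp
    profile = AllelicProfile(strain_id or records[0][0], tuple(numbers))
    return profile, registry.assign_st(profile), amplicons
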