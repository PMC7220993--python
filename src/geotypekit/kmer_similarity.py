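"""Presence/absence k-mer comparison of assembled genomes.

The distinct 31-mer content of an assembly ``i`` is a set ``A_i``; the
normalized shared-k-mer similarity between two assemblies is

    K'_ij = |A_i intersect A_j| / (|A_i| * |A_j|)

with the product of the distinct counts — not their geometric mean — in the
denominator, so the self-similarity of a genome with ``m`` distinct k-mers
is ``1/m``.  A cosine (square-root denominator) variant is available for
users who want self-similarity 1.  The similarity matrix is transformed to
Euclidean distances between its rows and clustered with UPGMA elsewhere.

k-mers are 2-bit encoded integers (exact set membership, no sketching);
k <= 31 keeps codes within 62 bits.  By default k-mers are canonical
(strand-folded: the lexicographic minimum of a window and its reverse
complement) because draft scaffolds have arbitrary orientation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .errors import (
    EmptyInputError,
    IncompatibleKmerSetsError,
    MatrixValidationError,
    UndefinedSimilarityError,
)
from .trees import DistanceMatrix

_CODE = np.full(256, -1, dtype=np.int8)
for _i, _b in enumerate(b"ACGT"):
    _CODE[_b] = _i

_BASES = "ACGT"


@dataclass(frozen=True)
class KmerSet:
    """The distinct k-mer content (presence/absence) of one assembly."""

    genome_id: str
    k: int
    kmers: frozenset[int]
    canonical: bool = True

    @property
    def n_distinct(self) -> int:
        return len(self.kmers)


def encode_kmer(kmer: str) -> int:
    code = 0
    for base in kmer:
        v = int(_CODE[ord(base)])
        if v < 0:
            raise ValueError(f"non-ACGT base {base!r} in k-mer")
        code = (code << 2) | v
    return code


def decode_kmer(code: int, k: int) -> str:
    out = []
    for _ in range(k):
        out.append(_BASES[code & 3])
        code >>= 2
    return "".join(reversed(out))


def _window_codes(seq: str, k: int) -> np.ndarray:
    """2-bit codes of all valid k-windows of one sequence (vectorized)."""
    raw = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    codes = _CODE[raw]
    if len(codes) < k:
        return np.empty(0, dtype=np.uint64)
    win = np.lib.stride_tricks.sliding_window_view(codes, k)
    valid = (win >= 0).all(axis=1)
    if not valid.any():
        return np.empty(0, dtype=np.uint64)
    win = win[valid].astype(np.uint64)
    weights = (np.uint64(4) ** np.arange(k - 1, -1, -1, dtype=np.uint64))
    return win @ weights


def extract_kmers(
    records: list[tuple[str, str]],
    k: int = 31,
    canonical: bool = True,
    genome_id: str = "",
) -> KmerSet:
    """Collect the distinct k-mers of a set of scaffolds.

    Windows containing any non-ACGT letter are skipped (the sequence is in
    effect split at ambiguous bases); duplicates count once.  If ``k``
    exceeds every scaffold length an empty set is returned with a warning,
    not an error.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > 31:
        raise ValueError("k > 31 exceeds the 2-bit 64-bit encoding")
    if not records:
        raise EmptyInputError("no scaffolds to extract k-mers from")
    gid = genome_id or records[0][0]
    chunks = []
    for _, seq in records:
        codes = _window_codes(seq.upper(), k)
        if codes.size:
            chunks.append(codes)
    if not chunks:
        warnings.warn(f"{gid}: no valid {k}-mer window in any scaffold")
        return KmerSet(gid, k, frozenset(), canonical)
    codes = np.concatenate(chunks)
    if canonical:
        codes = np.minimum(codes, _revcomp_codes(codes, k))
    return KmerSet(gid, k, frozenset(int(c) for c in np.unique(codes)), canonical)


def _revcomp_codes(codes: np.ndarray, k: int) -> np.ndarray:
    """Reverse-complement of 2-bit encoded k-mers, vectorized."""
    out = np.zeros_like(codes)
    c = codes.copy()
    for _ in range(k):
        out = (out << np.uint64(2)) | (np.uint64(3) - (c & np.uint64(3)))
        c >>= np.uint64(2)
    return out


def _check_compatible(a: KmerSet, b: KmerSet) -> None:
    if a.k != b.k or a.canonical != b.canonical:
        raise IncompatibleKmerSetsError(
            f"cannot compare k={a.k} canonical={a.canonical} "
            f"with k={b.k} canonical={b.canonical}"
        )


def shared_count(a: KmerSet, b: KmerSet) -> int:
    """|A_i intersect A_j| — the raw shared-k-mer count."""
    _check_compatible(a, b)
    return len(a.kmers & b.kmers)


def normalized_similarity(a: KmerSet, b: KmerSet, cosine: bool = False) -> float:
    """K' = |A n B| / (|A| * |B|); ``cosine=True`` uses the sqrt denominator."""
    _check_compatible(a, b)
    if not a.kmers or not b.kmers:
        raise UndefinedSimilarityError("similarity undefined for an empty k-mer set")
    denom = a.n_distinct * b.n_distinct
    if cosine:
        denom = denom**0.5
    return shared_count(a, b) / denom


def fraction_shared(a: KmerSet, b: KmerSet) -> float:
    """Shared fraction of the smaller genome's k-mer content, in percent."""
    _check_compatible(a, b)
    if not a.kmers or not b.kmers:
        raise UndefinedSimilarityError("fraction undefined for an empty k-mer set")
    return 100.0 * shared_count(a, b) / min(a.n_distinct, b.n_distinct)


@dataclass(frozen=True)
class SimilarityMatrix:
    """Symmetric matrix of K' similarities, self-similarity 1/|A_i|."""

    ids: tuple[str, ...]
    values: np.ndarray
    k: int
    normalized: bool = True

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        if v.shape != (len(self.ids), len(self.ids)):
            raise MatrixValidationError("similarity matrix shape mismatch")
        if not np.allclose(v, v.T):
            raise MatrixValidationError("similarity matrix is not symmetric")
        if (v < 0).any():
            raise MatrixValidationError("similarities must be >= 0")


def similarity_matrix(sets: list[KmerSet], cosine: bool = False) -> SimilarityMatrix:
    """All pairwise K' values, including the 1/|A_i| diagonal."""
    if not sets:
        raise EmptyInputError("no k-mer sets")
    n = len(sets)
    values = np.zeros((n, n))
    for i in range(n):
        for j in range(i, n):
            values[i, j] = values[j, i] = normalized_similarity(sets[i], sets[j], cosine)
    return SimilarityMatrix(tuple(s.genome_id for s in sets), values, sets[0].k)


def similarity_to_euclidean(sim: SimilarityMatrix) -> DistanceMatrix:
    """Euclidean distance between the rows of the similarity matrix.

    d(i, j) = || row_i - row_j ||_2, which is zero on the diagonal and obeys
    the triangle inequality by construction.
    """
    v = sim.values
    diff = v[:, None, :] - v[None, :, :]
    d = np.sqrt((diff**2).sum(axis=2))
    d = (d + d.T) / 2  # enforce exact symmetry against float noise
    np.fill_diagonal(d, 0.0)
    return DistanceMatrix(sim.ids, d)
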