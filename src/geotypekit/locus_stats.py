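"""Per-locus diversity statistics for MLST loci.

Covers the classic single-locus summary of an MLST scheme: segregating
(polymorphic) sites, the proportion of variable sites, alleles per variable
site, Nei-Gojobori (1986) dN/dS over distinct alleles, and the average
number of nucleotide differences between two populations.

Alignment columns containing a gap or ambiguity code are excluded wholly
from site counts (complete deletion, the DnaSP convention), not pairwise.
Report-style rounding is half-up to 2 decimals; internal values keep full
precision.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Optional

import numpy as np
from Bio.Data.CodonTable import standard_dna_table

from .errors import AlignmentLengthError, CodonError

_CODON_TABLE = dict(standard_dna_table.forward_table)
_STOPS = set(standard_dna_table.stop_codons)
_BASES = "ACGT"


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Decimal half-up rounding (2.675 -> 2.68), as printed reports use."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class LocusAlignment:
    """Equal-length nucleotide sequences for one locus."""

    locus: str
    sequences: tuple[tuple[str, str], ...]

    def __post_init__(self):
        seqs = tuple((sid, seq.upper()) for sid, seq in self.sequences)
        object.__setattr__(self, "sequences", seqs)
        lengths = {len(s) for _, s in seqs}
        if len(lengths) > 1:
            raise AlignmentLengthError(
                f"{self.locus}: unequal sequence lengths {sorted(lengths)}"
            )

    @property
    def length(self) -> int:
        return len(self.sequences[0][1]) if self.sequences else 0

    @property
    def n(self) -> int:
        return len(self.sequences)

    def column_matrix(self) -> np.ndarray:
        return np.array([list(seq) for _, seq in self.sequences])


@dataclass(frozen=True)
class LocusSummary:
    locus: str
    L: int
    S: int
    S_nonsyn: Optional[int]
    n_alleles: int
    pct_variable: float
    alleles_per_site: Optional[float]
    dN: Optional[float] = None
    dS: Optional[float] = None
    dnds: Optional[float] = None


def _clean_columns(aln: LocusAlignment) -> np.ndarray:
    """Boolean mask of columns free of gaps/ambiguity in every sequence."""
    cols = aln.column_matrix()
    return np.isin(cols, list(_BASES)).all(axis=0)


def segregating_sites(aln: LocusAlignment) -> int:
    """Columns with >= 2 distinct A/C/G/T states; unclean columns excluded."""
    if aln.n < 2:
        raise ValueError("need at least 2 sequences")
    cols = aln.column_matrix()
    clean = _clean_columns(aln)
    count = 0
    for j in np.flatnonzero(clean):
        if len(set(cols[:, j])) >= 2:
            count += 1
    return count


def distinct_alleles(aln: LocusAlignment) -> list[str]:
    """Distinct sequences in first-observation order."""
    seen, out = set(), []
    for _, seq in aln.sequences:
        if seq not in seen:
            seen.add(seq)
            out.append(seq)
    return out


def _nonsyn_segregating_sites(aln: LocusAlignment) -> int:
    """Polymorphic sites where some observed pair of sequences changes the
    encoded amino acid at that site's codon."""
    cols = aln.column_matrix()
    clean = _clean_columns(aln)
    seqs = [s for _, s in aln.sequences]
    count = 0
    for j in np.flatnonzero(clean):
        states = set(cols[:, j])
        if len(states) < 2:
            continue
        c0 = (j // 3) * 3
        codons = {s[c0 : c0 + 3] for s in seqs if set(s[c0 : c0 + 3]) <= set(_BASES)}
        aas = {_CODON_TABLE.get(c, "*") for c in codons}
        if len(aas) > 1:
            count += 1
    return count


def locus_summary(
    aln: LocusAlignment, L: Optional[int] = None, codon: bool = True
) -> LocusSummary:
    """Table-style per-locus summary.

    ``L`` defaults to the alignment length but can be set to the locus size
    of the typing scheme when the aligned region is a trimmed subset.
    ``pct_variable`` and ``alleles_per_site`` are half-up rounded to 2
    decimals; ``alleles_per_site`` is None when S = 0.
    """
    L = L if L is not None else aln.length
    S = segregating_sites(aln)
    n_alleles = len(distinct_alleles(aln))
    do_codon = codon and aln.length % 3 == 0
    s_nonsyn = _nonsyn_segregating_sites(aln) if do_codon else None
    dN = dS = ratio = None
    if do_codon and n_alleles >= 2:
        dN, dS, ratio = dnds(aln)
    return LocusSummary(
        locus=aln.locus,
        L=L,
        S=S,
        S_nonsyn=s_nonsyn,
        n_alleles=n_alleles,
        pct_variable=round_half_up(100.0 * S / L),
        alleles_per_site=round_half_up(n_alleles / S) if S > 0 else None,
        dN=dN,
        dS=dS,
        dnds=ratio,
    )


# ---------------------------------------------------------------------------
# Nei-Gojobori (1986) dN/dS
# ---------------------------------------------------------------------------

def _codon_sites(codon: str) -> tuple[float, float]:
    """(synonymous, nonsynonymous) site counts of one codon.

    Each position contributes the fraction of its three possible changes
    that are synonymous; changes creating a stop codon count as
    nonsynonymous.
    """
    aa = _CODON_TABLE.get(codon)
    if aa is None:
        raise CodonError(f"stop or invalid codon {codon!r}")
    syn = 0.0
    for pos in range(3):
        for base in _BASES:
            if base == codon[pos]:
                continue
            alt = codon[:pos] + base + codon[pos + 1 :]
            if _CODON_TABLE.get(alt) == aa:
                syn += 1 / 3
    return syn, 3.0 - syn


def _pathway_changes(c1: str, c2: str) -> tuple[float, float]:
    """(Sd, Nd) between two codons, averaged over mutational pathways.

    Pathways passing through a stop codon are excluded; if every pathway is
    blocked, all are used (the degenerate case of NG86 counting).
    """
    diff = [i for i in range(3) if c1[i] != c2[i]]
    if not diff:
        return 0.0, 0.0
    results = []
    for order in itertools.permutations(diff):
        cur, syn, nonsyn, blocked = c1, 0.0, 0.0, False
        for pos in order:
            nxt = cur[:pos] + c2[pos] + cur[pos + 1 :]
            if nxt in _STOPS and nxt != c2:
                blocked = True
                break
            a1, a2 = _CODON_TABLE.get(cur, "*"), _CODON_TABLE.get(nxt, "*")
            if a1 == a2:
                syn += 1
            else:
                nonsyn += 1
            cur = nxt
        if not blocked:
            results.append((syn, nonsyn))
    if not results:  # all pathways pass through stops
        for order in itertools.permutations(diff):
            cur, syn, nonsyn = c1, 0.0, 0.0
            for pos in order:
                nxt = cur[:pos] + c2[pos] + cur[pos + 1 :]
                a1, a2 = _CODON_TABLE.get(cur, "*"), _CODON_TABLE.get(nxt, "*")
                if a1 == a2:
                    syn += 1
                else:
                    nonsyn += 1
                cur = nxt
            results.append((syn, nonsyn))
    syn = sum(r[0] for r in results) / len(results)
    nonsyn = sum(r[1] for r in results) / len(results)
    return syn, nonsyn


def pairwise_ng86(seq1: str, seq2: str, jukes_cantor: bool = False):
    """NG86 (pN, pS) — or (dN, dS) with Jukes-Cantor — for one sequence pair.

    Codons containing a non-ACGT character in either sequence are excluded
    wholly.  Internal stop codons raise :class:`CodonError` naming the
    codon position.
    """
    if len(seq1) != len(seq2):
        raise AlignmentLengthError("sequences differ in length")
    if len(seq1) % 3:
        raise CodonError("sequence length is not a multiple of 3")
    S_sites = N_sites = Sd = Nd = 0.0
    ncodons = len(seq1) // 3
    for ci in range(ncodons):
        c1 = seq1[3 * ci : 3 * ci + 3]
        c2 = seq2[3 * ci : 3 * ci + 3]
        if set(c1) - set(_BASES) or set(c2) - set(_BASES):
            continue
        if c1 in _STOPS or c2 in _STOPS:
            if ci < ncodons - 1:
                raise CodonError(f"internal stop codon at codon {ci + 1}")
            continue  # terminal stop codon carries no countable sites
        s1, n1 = _codon_sites(c1)
        s2, n2 = _codon_sites(c2)
        S_sites += (s1 + s2) / 2
        N_sites += (n1 + n2) / 2
        sd, nd = _pathway_changes(c1, c2)
        Sd += sd
        Nd += nd
    pS = Sd / S_sites if S_sites else 0.0
    pN = Nd / N_sites if N_sites else 0.0
    if jukes_cantor:
        pS = _jc(pS)
        pN = _jc(pN)
    return pN, pS


def _jc(p: float) -> float:
    if p >= 0.75:
        raise ValueError(f"Jukes-Cantor correction undefined for p = {p}")
    return -0.75 * float(np.log(1 - 4 * p / 3))


def dnds(
    aln: LocusAlignment,
    jukes_cantor: bool = False,
    per_isolate: bool = False,
):
    """Average NG86 dN, dS and their ratio over sequence pairs.

    By default pairs of DISTINCT alleles are averaged (the statistics
    describe allele diversity, so duplicated isolates carry no extra
    weight); ``per_isolate=True`` averages over all isolate pairs instead.
    The ratio is 0 when no nonsynonymous change was seen, and None
    (undefined) when synonymous changes are absent while nonsynonymous ones
    exist.
    """
    if aln.length % 3:
        raise CodonError(f"{aln.locus}: length {aln.length} not a multiple of 3")
    seqs = [s for _, s in aln.sequences] if per_isolate else distinct_alleles(aln)
    pairs = list(itertools.combinations(seqs, 2))
    if not pairs:
        return 0.0, 0.0, 0.0
    pn_vals, ps_vals = [], []
    for s1, s2 in pairs:
        pn, ps = pairwise_ng86(s1, s2, jukes_cantor=jukes_cantor)
        pn_vals.append(pn)
        ps_vals.append(ps)
    dN = float(np.mean(pn_vals))
    dS = float(np.mean(ps_vals))
    if dN == 0.0:
        ratio: Optional[float] = 0.0
    elif dS == 0.0:
        ratio = None
    else:
        ratio = dN / dS
    return dN, dS, ratio


def avg_differences_between(popA: LocusAlignment, popB: LocusAlignment) -> float:
    """Mean pairwise nucleotide difference count across populations (Dxy,
    uncorrected): the average over all inter-population sequence pairs of
    the number of differing A/C/G/T positions."""
    if popA.length != popB.length:
        raise AlignmentLengthError("populations have different alignment lengths")
    acgt = np.frombuffer(b"ACGT", dtype="S1")
    total, npairs = 0, 0
    for _, sa in popA.sequences:
        a = np.frombuffer(sa.encode(), dtype="S1")
        for _, sb in popB.sequences:
            b = np.frombuffer(sb.encode(), dtype="S1")
            ok = np.isin(a, acgt) & np.isin(b, acgt)
            total += int(((a != b) & ok).sum())
            npairs += 1
    return total / npairs if npairs else 0.0
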