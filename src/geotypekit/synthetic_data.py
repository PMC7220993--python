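"""Synthetic inputs with known ground truth for every pipeline stage.

Four generators cover the input classes the pipeline consumes:

* clonal multilocus populations (a coalescent genealogy with per-branch
  Poisson mutation) — tree-like allele diversity, positive IA on average;
* linkage-equilibrium populations (independent Dirichlet-frequency draws
  per locus) — the recombination-dominated null, IA ~ 0;
* two-clade alignments with optional reciprocal crossover offspring — the
  power model for the phi recombination test;
* draft-genome sets (random scaffolds, optionally a shared core fraction
  controlling k-mer overlap, optionally planted MLST amplicons built from
  the real primer pairs).

Every generator is a pure function of its configuration, including the
seed, and emits a truth record (genealogy, crossover positions, planted
coordinates) so downstream tests are self-verifying.

Default sizes mirror the study the toolkit reproduces: 41 strains, six
loci, locus length 477 bp (the mean of the six scheme loci, rounded to a
codon multiple), and a mutation rate chosen to yield on the order of 60-75
polymorphic sites over the ~2.9 kb concatenate.  Genomes are scaled down
(tens of kb, not tens of Mb) — the k-mer similarity normalisation is
size-invariant, so nothing downstream depends on genome scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .errors import ConfigError
from .io_formats import LOCUS_ORDER, load_table3_fixture
from .linkage_stats import HaplotypeMatrix
from .locus_stats import LocusAlignment
from .mlst_typing import AlleleDatabase, revcomp

_BASES = np.array(list("ACGT"))
_STOPS = {"TAA", "TAG", "TGA"}


@dataclass(frozen=True)
class SimulationConfig:
    seed: int = 0
    n_strains: int = 41
    n_loci: int = 6
    alleles_per_locus: int = 8
    locus_length: int = 477  # codon multiple
    mutation_rate: float = 0.003  # per site (per unit branch length where relevant)
    crossover_rate: float = 0.0  # expected crossovers per recombinant lineage
    divergence: float = 0.08  # parental divergence for recombinant alignments
    n_scaffolds: int = 6
    scaffold_length: int = 20_000
    planted_loci: bool = True
    core_overlap_fraction: float = 0.0

    def __post_init__(self):
        if self.n_strains < 1 or self.n_loci < 1:
            raise ConfigError("n_strains and n_loci must be positive")
        if self.locus_length % 3:
            raise ConfigError("locus_length must be a multiple of 3")
        for name in ("mutation_rate", "divergence", "core_overlap_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name} must be in [0, 1], got {v}")
        if self.crossover_rate < 0:
            raise ConfigError("crossover_rate must be >= 0")


def _random_seq(rng, length: int) -> str:
    return "".join(rng.choice(_BASES, size=length))


def _random_coding_seq(rng, length: int) -> str:
    """Random sequence of non-stop codons (an open reading frame)."""
    codons = []
    while len(codons) * 3 < length:
        c = "".join(rng.choice(_BASES, size=3))
        if c not in _STOPS:
            codons.append(c)
    return "".join(codons)[:length]


def _mutate_coding(rng, seq: str, n_mut: int) -> str:
    """Apply point mutations, redrawing targets that would create a stop."""
    s = list(seq)
    for _ in range(n_mut):
        pos = int(rng.integers(len(s)))
        options = [b for b in "ACGT" if b != s[pos]]
        rng.shuffle(options)
        for b in options:
            old = s[pos]
            s[pos] = b
            c0 = (pos // 3) * 3
            if "".join(s[c0 : c0 + 3]) not in _STOPS:
                break
            s[pos] = old
    return "".join(s)


# ---------------------------------------------------------------------------
# Populations
# ---------------------------------------------------------------------------

def _coalescent_tree(rng, n: int):
    """Random binary genealogy; returns (children, branch_length, root).

    Node ids: 0..n-1 are leaves; internal nodes follow.  Branch lengths are
    in coalescent units (exponential waiting times while k lineages remain).
    """
    children: dict[int, tuple[int, int]] = {}
    blen = np.zeros(2 * n - 1)
    birth = np.zeros(2 * n - 1)  # time each lineage became active
    active = list(range(n))
    t = 0.0
    nxt = n
    while len(active) > 1:
        k = len(active)
        t += rng.exponential(2.0 / (k * (k - 1)))
        i, j = sorted(rng.choice(k, size=2, replace=False))
        a, b = active[i], active[j]
        blen[a] = t - birth[a]
        blen[b] = t - birth[b]
        children[nxt] = (a, b)
        birth[nxt] = t
        active[j] = nxt
        active.pop(i)
        nxt += 1
    return children, blen, nxt - 1


def _genealogy_newick(children, blen, node, labels) -> str:
    if node not in children:
        return f"{labels[node]}:{blen[node]:.6f}"
    a, b = children[node]
    inner = ",".join(_genealogy_newick(children, blen, c, labels) for c in (a, b))
    suffix = f":{blen[node]:.6f}" if blen[node] else ""
    return f"({inner}){suffix}"


def simulate_clonal_population(cfg: SimulationConfig):
    """Clonal descent: one genealogy shared by all loci, mutation only.

    Returns ``(HaplotypeMatrix, {locus: LocusAlignment}, genealogy_newick)``.
    Allele numbers are assigned by order of discovery in strain order, so
    the matrix is a deterministic function of the configuration.
    """
    if cfg.crossover_rate:
        raise ConfigError("clonal population requires crossover_rate = 0")
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_strains
    strain_ids = tuple(f"S{i + 1:03d}" for i in range(n))
    children, blen, root = _coalescent_tree(rng, n) if n > 1 else ({}, np.zeros(1), 0)

    loci = tuple(
        LOCUS_ORDER[i] if i < len(LOCUS_ORDER) else f"LOC{i + 1}"
        for i in range(cfg.n_loci)
    )
    alignments: dict[str, LocusAlignment] = {}
    profile = np.zeros((n, cfg.n_loci), dtype=int)
    for j, locus in enumerate(loci):
        root_seq = _random_coding_seq(rng, cfg.locus_length)
        leaf_seqs: dict[int, str] = {}
        stack = [(root, root_seq)]
        while stack:
            node, seq = stack.pop()
            if node < n:
                leaf_seqs[node] = seq
                continue
            for child in children[node]:
                n_mut = rng.poisson(cfg.mutation_rate * cfg.locus_length * blen[child])
                stack.append((child, _mutate_coding(rng, seq, int(n_mut))))
        aln = LocusAlignment(locus, tuple((strain_ids[i], leaf_seqs[i]) for i in range(n)))
        alignments[locus] = aln
        db = AlleleDatabase(locus)
        for i in range(n):
            profile[i, j] = db.assign_allele(leaf_seqs[i])
    matrix = HaplotypeMatrix(strain_ids, loci, profile)
    newick = _genealogy_newick(children, blen, root, strain_ids) + ";" if n > 1 else f"{strain_ids[0]};"
    return matrix, alignments, newick


def simulate_equilibrium_population(cfg: SimulationConfig) -> HaplotypeMatrix:
    """Linkage equilibrium: each locus drawn independently.

    Per-locus allele frequencies come from a flat Dirichlet over
    ``alleles_per_locus`` alleles; strains are independent draws, so
    inter-locus independence holds by construction.
    """
    rng = np.random.default_rng(cfg.seed)
    n, l, a = cfg.n_strains, cfg.n_loci, cfg.alleles_per_locus
    profile = np.zeros((n, l), dtype=int)
    for j in range(l):
        freqs = rng.dirichlet(np.ones(a))
        profile[:, j] = rng.choice(a, size=n, p=freqs) + 1
    loci = tuple(
        LOCUS_ORDER[i] if i < len(LOCUS_ORDER) else f"LOC{i + 1}" for i in range(l)
    )
    return HaplotypeMatrix(tuple(f"S{i + 1:03d}" for i in range(n)), loci, profile)


# ---------------------------------------------------------------------------
# Recombinant alignments
# ---------------------------------------------------------------------------

def simulate_recombinant_alignment(
    cfg: SimulationConfig, n_crossovers: Optional[int] = None
):
    """Two divergent parental clades, optionally with crossover offspring.

    The two parents differ at each site with probability ``divergence``.
    Non-recombinant strains copy one parent with light mutational noise.
    When crossovers are requested (``n_crossovers`` or a positive
    ``crossover_rate``), one RECIPROCAL pair of recombinants is produced —
    both crossover products, as a physical crossover yields — with the
    breakpoints recorded in the truth dict.

    Returns ``(LocusAlignment, truth)`` where truth holds ``parents``,
    ``breakpoints`` and per-strain clade assignments.
    """
    rng = np.random.default_rng(cfg.seed)
    L = cfg.locus_length
    parent_a = _random_seq(rng, L)
    pb = list(parent_a)
    for pos in np.flatnonzero(rng.random(L) < cfg.divergence):
        pb[pos] = rng.choice([b for b in "ACGT" if b != pb[pos]])
    parent_b = "".join(pb)

    if n_crossovers is None:
        n_crossovers = int(rng.poisson(cfg.crossover_rate)) if cfg.crossover_rate else 0
    breakpoints = sorted(int(x) for x in rng.integers(1, L, size=n_crossovers))

    def recombine(first: str, second: str) -> str:
        out, cur, alt, prev = [], first, second, 0
        for bp in breakpoints + [L]:
            out.append(cur[prev:bp])
            cur, alt = alt, cur
            prev = bp
        return "".join(out)

    n_children = 2 if breakpoints else 0
    n_backbone = cfg.n_strains - n_children
    if n_backbone < 4:
        raise ConfigError("n_strains too small for two clades plus offspring")
    half = n_backbone // 2

    sequences, clades = [], {}
    idx = 1
    for clade, parent, count in (("A", parent_a, half), ("B", parent_b, n_backbone - half)):
        for _ in range(count):
            n_mut = int(rng.poisson(cfg.mutation_rate * L))
            seq = parent
            if n_mut:
                s = list(seq)
                for pos in rng.integers(0, L, size=n_mut):
                    s[pos] = rng.choice([b for b in "ACGT" if b != s[pos]])
                seq = "".join(s)
            sid = f"S{idx:03d}"
            sequences.append((sid, seq))
            clades[sid] = clade
            idx += 1
    for seq, clade in ((recombine(parent_a, parent_b), "AxB"),
                       (recombine(parent_b, parent_a), "BxA")) if breakpoints else ():
        sid = f"S{idx:03d}"
        sequences.append((sid, seq))
        clades[sid] = clade
        idx += 1

    truth = {
        "parents": (parent_a, parent_b),
        "breakpoints": breakpoints,
        "clades": clades,
    }
    return LocusAlignment("SIM", tuple(sequences)), truth


# ---------------------------------------------------------------------------
# Draft genomes
# ---------------------------------------------------------------------------

def simulate_genomes(cfg: SimulationConfig):
    """Scaled-down draft assemblies with optional planted loci / shared core.

    Returns ``(genomes, allele_pool, truth)``:

    * ``genomes``: ``{strain_id: [(scaffold_id, sequence), ...]}``;
    * ``allele_pool``: ``{locus: [amplicon variant sequences]}`` (full
      amplicons, primer annealing sites included, built from the packaged
      primer pairs);
    * ``truth``: rows ``{strain, locus, allele_idx, scaffold, start, end,
      strand, amplicon}`` with 0-based half-open forward-strand coordinates.

    ``core_overlap_fraction`` carves that fraction of every genome out of
    one shared sequence, giving pairs a controlled k-mer overlap.
    """
    rng = np.random.default_rng(cfg.seed)
    total = cfg.n_scaffolds * cfg.scaffold_length
    core_len = int(round(cfg.core_overlap_fraction * total))
    core = _random_seq(rng, core_len) if core_len else ""
    chunk = -(-core_len // cfg.n_scaffolds) if core_len else 0  # ceil division

    allele_pool: dict[str, list[str]] = {}
    primers = {p.locus: p for p in load_table3_fixture() if p.mlst2019}
    if cfg.planted_loci:
        for locus in LOCUS_ORDER:
            p = primers[locus]
            insert_len = p.locus_size - len(p.forward) - len(p.reverse)
            base_insert = _random_coding_seq(rng, insert_len)
            variants = []
            seen = set()
            while len(variants) < cfg.alleles_per_locus:
                if not variants:
                    insert = base_insert
                else:
                    # a few substitutions, kept clear of the trailing bases a
                    # codon trim may drop, so every variant is a new allele
                    insert = _mutate_coding(rng, base_insert, len(variants))
                amp = p.forward + insert + revcomp(p.reverse)
                if amp not in seen:
                    seen.add(amp)
                    variants.append(amp)
            allele_pool[locus] = variants

    genomes: dict[str, list[tuple[str, str]]] = {}
    truth: list[dict] = []
    for i in range(cfg.n_strains):
        sid = f"G{i + 1:03d}"
        scaffolds = []
        for s in range(cfg.n_scaffolds):
            shared = core[s * chunk : (s + 1) * chunk] if core else ""
            fill = _random_seq(rng, cfg.scaffold_length - len(shared))
            scaffolds.append([f"{sid}_scaf{s + 1}", shared + fill])
        if cfg.planted_loci:
            occupied: dict[int, list[tuple[int, int]]] = {s: [] for s in range(cfg.n_scaffolds)}
            for locus in LOCUS_ORDER:
                variants = allele_pool[locus]
                allele_idx = int(rng.integers(len(variants)))
                amp = variants[allele_idx]
                strand = "+" if rng.random() < 0.5 else "-"
                planted = amp if strand == "+" else revcomp(amp)
                for _ in range(1000):
                    s = int(rng.integers(cfg.n_scaffolds))
                    start = int(rng.integers(0, cfg.scaffold_length - len(planted)))
                    end = start + len(planted)
                    if all(not (start < e and b < end) for b, e in occupied[s]):
                        break
                else:  # pragma: no cover - only with absurdly dense configs
                    raise ConfigError("could not place planted locus without overlap")
                occupied[s].append((start, end))
                name, seq = scaffolds[s]
                scaffolds[s] = [name, seq[:start] + planted + seq[end:]]
                truth.append(
                    dict(strain=sid, locus=locus, allele_idx=allele_idx,
                         scaffold=name, start=start, end=end, strand=strand,
                         amplicon=amp)
                )
        genomes[sid] = [tuple(sc) for sc in scaffolds]
    return genomes, allele_pool, truth
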