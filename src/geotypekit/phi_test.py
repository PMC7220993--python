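"""Pairwise homoplasy index (phi) test for recombination.

Recombination leaves a spatial signature: nearby alignment sites tend to
share one genealogy (and so are mutually compatible) while distant sites
may not.  The phi statistic is the mean refined incompatibility over all
pairs of parsimony-informative sites that lie within a window ``w`` of each
other in the informative-site ordering.  Significance comes from permuting
the site order: under clonal evolution incompatibility has no spatial
structure, so the observed windowed mean is exchangeable with the permuted
ones.  A small p-value (observed mean unusually LOW relative to permuted
site orders) indicates recombination.

Refined incompatibility between two sites with ``a`` and ``b`` observed
states is ``max(0, (distinct joint state pairs) - (a + b - 1))``; for
binary sites this is exactly the four-gamete test indicator.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .errors import InsufficientTaxaError
from .locus_stats import LocusAlignment

_BASES = set("ACGT")


@dataclass(frozen=True)
class InformativeSiteSet:
    """Parsimony-informative sites of an alignment.

    ``states`` is an (n_sequences x n_sites) integer matrix; ``positions``
    are the original 0-based alignment coordinates, strictly increasing.
    """

    positions: tuple[int, ...]
    states: np.ndarray

    @property
    def n_sites(self) -> int:
        return len(self.positions)


def informative_sites(aln: LocusAlignment) -> InformativeSiteSet:
    """Columns with >= 2 states each carried by >= 2 sequences.

    Columns containing a gap or ambiguity letter are dropped, as are
    singleton-variant columns (not informative for incompatibility).
    """
    if aln.n < 4:
        raise InsufficientTaxaError("phi preprocessing needs >= 4 sequences")
    cols = aln.column_matrix()
    positions, state_cols = [], []
    for j in range(cols.shape[1]):
        col = cols[:, j]
        if set(col) - _BASES:
            continue
        values, counts = np.unique(col, return_counts=True)
        if (counts >= 2).sum() >= 2:
            # re-encode states as consecutive ints; rare singleton states at
            # an otherwise informative column are kept as their own state
            mapping = {v: i for i, v in enumerate(values)}
            positions.append(j)
            state_cols.append([mapping[v] for v in col])
    states = (
        np.array(state_cols).T if state_cols else np.empty((aln.n, 0), dtype=int)
    )
    return InformativeSiteSet(tuple(positions), states)


def pair_incompatibility(site_a: np.ndarray, site_b: np.ndarray) -> int:
    """Refined incompatibility score of two site columns (0 = compatible).

    The score counts how many joint states exceed the ``a + b - 1`` that a
    single tree can explain; it is symmetric, and zero iff the two sites
    are congruent with one genealogy (four-gamete test for binary sites).
    """
    a = len(set(site_a.tolist()))
    b = len(set(site_b.tolist()))
    joint = len(set(zip(site_a.tolist(), site_b.tolist())))
    return max(0, joint - (a + b - 1))


def incompatibility_matrix(sites: InformativeSiteSet) -> np.ndarray:
    m = sites.n_sites
    mat = np.zeros((m, m), dtype=int)
    for i in range(m):
        for j in range(i + 1, m):
            score = pair_incompatibility(sites.states[:, i], sites.states[:, j])
            mat[i, j] = mat[j, i] = score
    return mat


@dataclass(frozen=True)
class PhiResult:
    phi_mean: float
    n_informative: int
    window_w: int
    p_value: Optional[float]
    n_permutations: int
    seed: Optional[int]

    @property
    def testable(self) -> bool:
        return self.p_value is not None


def _rank_pairs(m: int, w: int) -> tuple[np.ndarray, np.ndarray]:
    """Rank index pairs (r1 < r2 <= r1 + w); fixed across permutations."""
    r1, r2 = np.triu_indices(m, k=1)
    keep = (r2 - r1) <= w
    return r1[keep], r2[keep]


def _windowed_mean(mat, order, r1, r2) -> float:
    if len(r1) == 0:
        return 0.0
    return float(mat[order[r1], order[r2]].mean())


def phi(
    aln: LocusAlignment,
    window_w: int = 100,
    n_permutations: int = 1000,
    seed: int = 0,
) -> PhiResult:
    """Windowed mean incompatibility with a site-order permutation test.

    ``p = (1 + #{phi* <= phi_obs}) / (1 + n_permutations)`` — small when
    nearby sites are more compatible than a random arrangement of the same
    sites, the hallmark of recombination.  With fewer than two informative
    sites the result is not testable (``p_value`` is None).  Note that when
    all site pairs fall inside the window the statistic is permutation-
    invariant and p is 1 by construction; pick ``window_w`` below the
    informative-site count for a meaningful test.
    """
    sites = informative_sites(aln)
    m = sites.n_sites
    if m < 2:
        return PhiResult(0.0, m, window_w, None, 0, seed)
    mat = incompatibility_matrix(sites)
    r1, r2 = _rank_pairs(m, window_w)
    order = np.arange(m)  # positions are already in coordinate order
    observed = _windowed_mean(mat, order, r1, r2)
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_permutations):
        if _windowed_mean(mat, rng.permutation(m), r1, r2) <= observed:
            hits += 1
    p = (1 + hits) / (1 + n_permutations)
    return PhiResult(observed, m, window_w, p, n_permutations, seed)
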