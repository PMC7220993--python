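"""Distance-based clustering (UPGMA, neighbor-joining) and Newick output.

UPGMA is implemented here rather than delegated so that tie-breaking is
fully deterministic: when several cluster pairs attain the minimum average
distance, the pair with the smallest (row, column) index in the current
cluster ordering is merged, so the dendrogram is bit-stable across runs.
Node height is half the merge distance, which makes the result ultrametric.
Neighbor joining is plumbing and delegates to scikit-bio.

Trees are scikit-bio ``TreeNode`` objects, so Newick serialisation and
re-parsing come for free.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass

import numpy as np
import skbio
from skbio.tree import TreeNode

from .errors import IncompleteProfileError, MatrixValidationError
from .linkage_stats import MISSING, HaplotypeMatrix


@dataclass(frozen=True)
class DistanceMatrix:
    """Symmetric non-negative distance matrix with a zero diagonal."""

    ids: tuple[str, ...]
    d: np.ndarray

    def __post_init__(self):
        d = np.asarray(self.d, dtype=float)
        object.__setattr__(self, "d", d)
        object.__setattr__(self, "ids", tuple(self.ids))
        n = len(self.ids)
        if d.shape != (n, n):
            raise MatrixValidationError(f"matrix shape {d.shape} does not match {n} ids")
        if not np.allclose(d, d.T):
            raise MatrixValidationError("distance matrix is not symmetric")
        if not np.allclose(np.diag(d), 0.0):
            raise MatrixValidationError("distance matrix diagonal is not zero")
        if (d < 0).any():
            raise MatrixValidationError("distances must be >= 0")

    @property
    def n(self) -> int:
        return len(self.ids)


def upgma(dm: DistanceMatrix) -> TreeNode:
    """Average-linkage agglomeration; returns a rooted ultrametric tree.

    Each merge joins the pair of clusters with the smallest average
    distance; the new node sits at height d/2 and inter-cluster distances
    are size-weighted averages (classic UPGMA).
    """
    if dm.n < 2:
        raise ValueError("UPGMA needs at least 2 taxa")
    nodes = [TreeNode(name=name, length=None) for name in dm.ids]
    heights = [0.0] * dm.n
    sizes = [1] * dm.n
    d = dm.d.copy()
    active = list(range(dm.n))

    while len(active) > 1:
        # smallest distance; ties broken by smallest (row, column) position
        best = None
        for ai in range(len(active)):
            for aj in range(ai + 1, len(active)):
                dij = d[active[ai], active[aj]]
                if best is None or dij < best[0] - 1e-15:
                    best = (dij, ai, aj)
        dij, ai, aj = best
        i, j = active[ai], active[aj]
        h = dij / 2.0
        parent = TreeNode(length=None)
        for child_idx in (i, j):
            child = nodes[child_idx]
            child.length = h - heights[child_idx]
            parent.append(child)
        # merged cluster replaces position ai; distances are weighted means
        ni, nj = sizes[i], sizes[j]
        for other in active:
            if other in (i, j):
                continue
            dnew = (ni * d[i, other] + nj * d[j, other]) / (ni + nj)
            d[i, other] = d[other, i] = dnew
        nodes[i] = parent
        heights[i] = h
        sizes[i] = ni + nj
        active.pop(aj)

    root = nodes[active[0]]
    root.length = None
    return root


def neighbor_joining(dm: DistanceMatrix) -> TreeNode:
    """Classical NJ via scikit-bio; negative branch lengths clamped to 0."""
    skdm = skbio.DistanceMatrix(dm.d, ids=list(dm.ids))
    tree = skbio.tree.nj(skdm)
    clamped = 0
    for node in tree.traverse():
        if node.length is not None and node.length < 0:
            node.length = 0.0
            clamped += 1
    if clamped:
        warnings.warn(f"clamped {clamped} negative NJ branch lengths to 0")
    return tree


def profile_distance(a, b) -> int:
    """Number of loci at which two allelic profiles differ (0..l)."""
    aa, bb = tuple(a), tuple(b)
    if len(aa) != len(bb):
        raise ValueError("profiles cover different numbers of loci")
    if MISSING in aa or MISSING in bb or None in aa or None in bb:
        raise IncompleteProfileError("profiles with missing alleles are not comparable")
    return sum(x != y for x, y in zip(aa, bb))


def profile_distance_matrix(m: HaplotypeMatrix) -> DistanceMatrix:
    """Pairwise locus-mismatch distances over all strains of a matrix."""
    a = m.alleles
    if (a == MISSING).any():
        raise IncompleteProfileError("matrix contains missing alleles")
    d = (a[:, None, :] != a[None, :, :]).sum(axis=2).astype(float)
    return DistanceMatrix(m.strain_ids, d)


def write_newick(tree: TreeNode, path=None) -> str:
    buf = io.StringIO()
    tree.write(buf, format="newick")
    text = buf.getvalue()
    if path is not None:
        with open(path, "w") as out:
            out.write(text)
    return text


def read_newick(source) -> TreeNode:
    if isinstance(source, str) and "(" in source:
        return TreeNode.read(io.StringIO(source), format="newick")
    return TreeNode.read(str(source), format="newick")


def leaf_depths(tree: TreeNode) -> dict[str, float]:
    """Root-to-leaf path lengths, treating missing lengths as 0."""
    depths = {}
    for tip in tree.tips():
        total, node = 0.0, tip
        while node.parent is not None:
            total += node.length or 0.0
            node = node.parent
        depths[tip.name] = total
    return depths


def is_ultrametric(tree: TreeNode, tol: float = 1e-9) -> bool:
    depths = list(leaf_depths(tree).values())
    return max(depths) - min(depths) <= tol
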