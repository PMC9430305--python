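"""Kimura two-parameter distances, neighbor joining and bootstrap support.

The three LTR subtypes were originally delineated by phylogenetic
analysis; this module provides a deterministic, distance-based surrogate
(K2P + NJ + column-resampling bootstrap) whose acceptance surface is the
gross clade structure: the LTR5Hs clade cleanly separated, LTR5A nested
within LTR5B.  Maximum-likelihood search is deliberately out of scope.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .sequence_io import PairwiseAlignment, SequenceRecord, global_align

PURINES = frozenset("AG")
PYRIMIDINES = frozenset("CT")

#: distance assigned to saturated pairs (1 − 2P − Q ≤ 0 or 1 − 2Q ≤ 0)
SATURATION_CEILING = 5.0


class SaturationError(ValueError):
    """K2P distance undefined: substitution proportions are saturated."""


@dataclass
class DistanceMatrix:
    labels: list[str]
    d: np.ndarray
    saturated: list[tuple[str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=float)
        n = len(self.labels)
        if self.d.shape != (n, n):
            raise ValueError("matrix shape does not match labels")
        if not np.allclose(self.d, self.d.T):
            raise ValueError("distance matrix is not symmetric")
        if np.any(np.diag(self.d) != 0):
            raise ValueError("diagonal must be zero")


@dataclass
class TreeNode:
    """Node of an (un)rooted phylogeny with branch lengths and supports."""

    name: str | None = None
    length: float = 0.0
    support: float | None = None
    children: list["TreeNode"] = field(default_factory=list)
    negative_clamped: bool = False

    def leaves(self) -> list["TreeNode"]:
        if not self.children:
            return [self]
        out = []
        for c in self.children:
            out.extend(c.leaves())
        return out

    def leaf_names(self) -> list[str]:
        return [l.name for l in self.leaves()]

    def newick(self, with_support: bool = True) -> str:
        return self._newick(with_support) + ";"

    def _newick(self, with_support: bool) -> str:
        if not self.children:
            return f"{self.name}:{self.length:.6f}"
        inner = ",".join(c._newick(with_support) for c in self.children)
        label = ""
        if with_support and self.support is not None:
            label = f"{self.support:.2f}"
        return f"({inner}){label}:{self.length:.6f}"


def k2p_counts(a: str, b: str) -> tuple[int, int, int]:
    """(gap-free sites, transitions, transversions) over paired columns."""
    sites = ts = tv = 0
    for x, y in zip(a, b):
        if x == "-" or y == "-" or x == "N" or y == "N":
            continue
        sites += 1
        if x == y:
            continue
        same_class = ({x, y} <= PURINES) or ({x, y} <= PYRIMIDINES)
        if same_class:
            ts += 1
        else:
            tv += 1
    return sites, ts, tv


def k2p_distance(a: str, b: str, ceiling: float | None = SATURATION_CEILING
                 ) -> float:
    """Kimura 2-parameter distance in substitutions/site.

    ``d = -1/2 ln(1 - 2P - Q) - 1/4 ln(1 - 2Q)`` with P and Q the
    transition and transversion proportions over gap-free columns of the
    pre-aligned inputs.  Saturated pairs raise :class:`SaturationError`
    when ``ceiling`` is None, otherwise return the ceiling.
    """
    if len(a) != len(b):
        raise ValueError("k2p_distance requires pre-aligned, equal-length rows")
    sites, ts, tv = k2p_counts(a, b)
    if sites == 0:
        raise ValueError("no comparable (gap-free) sites")
    p, q = ts / sites, tv / sites
    w1 = 1.0 - 2.0 * p - q
    w2 = 1.0 - 2.0 * q
    if w1 <= 0 or w2 <= 0:
        if ceiling is None:
            raise SaturationError(f"saturated pair (P={p:.3f}, Q={q:.3f})")
        return ceiling
    return -0.5 * math.log(w1) - 0.25 * math.log(w2)


_CODE = {65: 0, 67: 1, 71: 2, 84: 3}  # A C G T; anything else excluded


def _encode(seqs: list[str]) -> np.ndarray:
    """(n, L) int8 matrix: A/C/G/T → 0..3, N or gap → −1."""
    raw = np.frombuffer("".join(seqs).encode(), dtype=np.uint8)
    mat = np.full(raw.shape, -1, dtype=np.int8)
    for byte, code in _CODE.items():
        mat[raw == byte] = code
    return mat.reshape(len(seqs), -1)


def _k2p_matrix(mat: np.ndarray, labels: list[str]
                ) -> tuple[np.ndarray, list[tuple[str, str]]]:
    n = mat.shape[0]
    valid = mat >= 0
    purine = (mat == 0) | (mat == 2)
    d = np.zeros((n, n))
    saturated: list[tuple[str, str]] = []
    for i in range(n):
        for j in range(i + 1, n):
            both = valid[i] & valid[j]
            sites = int(both.sum())
            if sites == 0:
                raise ValueError("no comparable (gap-free) sites")
            diff = both & (mat[i] != mat[j])
            ts = int((diff & (purine[i] == purine[j])).sum())
            tv = int(diff.sum()) - ts
            p, q = ts / sites, tv / sites
            w1, w2 = 1.0 - 2.0 * p - q, 1.0 - 2.0 * q
            if w1 <= 0 or w2 <= 0:
                dij = SATURATION_CEILING
                saturated.append((labels[i], labels[j]))
            else:
                dij = -0.5 * math.log(w1) - 0.25 * math.log(w2)
            d[i, j] = d[j, i] = dij
    return d, saturated


def distance_matrix(records: list[SequenceRecord],
                    aligned: bool | None = None) -> DistanceMatrix:
    """All-pairs K2P distances.

    If sequences are equal length (or ``aligned=True``) they are compared
    column-wise directly; otherwise each pair is globally aligned first and
    gap columns excluded per pair.
    """
    labels = [r.id for r in records]
    same_len = len({len(r.seq) for r in records}) == 1
    use_aligned = same_len if aligned is None else aligned
    if use_aligned:
        d, saturated = _k2p_matrix(_encode([r.seq for r in records]), labels)
        return DistanceMatrix(labels=labels, d=d, saturated=saturated)
    n = len(records)
    d = np.zeros((n, n))
    saturated = []
    for i in range(n):
        for j in range(i + 1, n):
            aln = global_align(records[i], records[j])
            try:
                dij = k2p_distance(aln.aligned_a, aln.aligned_b, ceiling=None)
            except SaturationError:
                dij = SATURATION_CEILING
                saturated.append((labels[i], labels[j]))
            d[i, j] = d[j, i] = dij
    return DistanceMatrix(labels=labels, d=d, saturated=saturated)


def nj_tree(dm: DistanceMatrix) -> TreeNode:
    """Canonical neighbor joining with deterministic tie-breaking.

    At each step the pair with the lowest Q-criterion is joined; exact ties
    are resolved by (label, label) order.  Negative branch lengths are
    clamped to zero and flagged on the node.  For 3 taxa the unique
    unrooted star resolution with closed-form branch lengths is returned.
    """
    n = len(dm.labels)
    if n < 3:
        raise ValueError("neighbor joining requires at least 3 taxa")
    nodes: list[TreeNode] = [TreeNode(name=l) for l in dm.labels]
    d = dm.d.astype(float).copy()
    active = list(range(n))

    def set_length(node: TreeNode, length: float) -> None:
        node.negative_clamped = length < 0
        node.length = max(0.0, length)

    while len(active) > 3:
        m = len(active)
        sub = d[np.ix_(active, active)]
        r = sub.sum(axis=1)
        q = (m - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        # deterministic argmin: lowest Q, ties by (label_i, label_j)
        best = None
        for ii in range(m):
            for jj in range(ii + 1, m):
                key = (q[ii, jj],
                       nodes[active[ii]].name or "",
                       nodes[active[jj]].name or "")
                if best is None or key < best[0]:
                    best = (key, ii, jj)
        _, ii, jj = best
        i, j = active[ii], active[jj]
        dij = d[i, j]
        li = 0.5 * dij + (r[ii] - r[jj]) / (2.0 * (m - 2))
        lj = dij - li
        parent = TreeNode()
        set_length(nodes[i], li)
        set_length(nodes[j], lj)
        parent.children = [nodes[i], nodes[j]]
        # distances from the new node to the remaining taxa
        new_row = 0.5 * (d[i, :] + d[j, :] - dij)
        d = np.vstack([d, new_row])
        d = np.hstack([d, np.append(new_row, 0.0)[:, None]])
        nodes.append(parent)
        active = [a for a in active if a not in (i, j)] + [len(nodes) - 1]

    i, j, k = active
    root = TreeNode()
    li = 0.5 * (d[i, j] + d[i, k] - d[j, k])
    lj = 0.5 * (d[i, j] + d[j, k] - d[i, k])
    lk = 0.5 * (d[i, k] + d[j, k] - d[i, j])
    for idx, length in ((i, li), (j, lj), (k, lk)):
        set_length(nodes[idx], length)
    root.children = [nodes[i], nodes[j], nodes[k]]
    return root


def bipartitions(tree: TreeNode) -> set[frozenset[str]]:
    """Non-trivial bipartitions of an unrooted tree.

    Each internal edge is encoded by the smaller (then lexicographically
    first) side of the leaf split, so representation is orientation-free.
    """
    all_leaves = frozenset(tree.leaf_names())
    out: set[frozenset[str]] = set()

    def canon(side: frozenset[str]) -> frozenset[str]:
        other = all_leaves - side
        if len(side) < len(other):
            return side
        if len(other) < len(side):
            return other
        return min(side, other, key=lambda s: sorted(s))

    def walk(node: TreeNode) -> frozenset[str]:
        if not node.children:
            return frozenset([node.name])
        below = frozenset().union(*(walk(c) for c in node.children))
        if node is not tree and 1 < len(below) < len(all_leaves) - 1:
            out.add(canon(below))
        return below

    walk(tree)
    return out


def _annotate_supports(tree: TreeNode, support: dict[frozenset[str], float]
                       ) -> None:
    all_leaves = frozenset(tree.leaf_names())

    def walk(node: TreeNode) -> frozenset[str]:
        if not node.children:
            return frozenset([node.name])
        below = frozenset().union(*(walk(c) for c in node.children))
        if node is not tree and 1 < len(below) < len(all_leaves) - 1:
            other = all_leaves - below
            key = below if len(below) < len(other) else (
                other if len(other) < len(below)
                else min(below, other, key=lambda s: sorted(s)))
            node.support = support.get(key, 0.0)
        return below

    walk(tree)


def bootstrap_support(records: list[SequenceRecord], n_reps: int = 1000,
                      seed: int = 0) -> TreeNode:
    """NJ tree with bootstrap supports from alignment-column resampling.

    Requires equal-length (aligned) rows.  Support of each original
    bipartition is the fraction of ``n_reps`` column-resampled replicate
    NJ trees that contain it, reported in [0, 1].  Deterministic for a
    fixed seed.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    lengths = {len(r.seq) for r in records}
    if len(lengths) != 1:
        raise ValueError("bootstrap requires aligned, equal-length rows")
    length = lengths.pop()
    rng = np.random.default_rng(seed)
    labels = [r.id for r in records]
    mat = _encode([r.seq for r in records])
    base = nj_tree(distance_matrix(records, aligned=True))
    counts = {bp: 0 for bp in bipartitions(base)}
    for _ in range(n_reps):
        cols = rng.integers(0, length, size=length)
        d, _sat = _k2p_matrix(mat[:, cols], labels)
        rep_tree = nj_tree(DistanceMatrix(labels=labels, d=d))
        for bp in bipartitions(rep_tree):
            if bp in counts:
                counts[bp] += 1
    support = {bp: c / n_reps for bp, c in counts.items()}
    _annotate_supports(base, support)
    return base


def clade_support(tree: TreeNode, leaf_names: set[str]) -> float | None:
    """Support of the bipartition separating exactly ``leaf_names``, if present."""
    target = frozenset(leaf_names)
    all_leaves = frozenset(tree.leaf_names())
    other = all_leaves - target
    key = target if len(target) < len(other) else (
        other if len(other) < len(target)
        else min(target, other, key=lambda s: sorted(s)))
    if key not in bipartitions(tree):
        return None

    found: list[float] = []

    def walk(node: TreeNode) -> frozenset[str]:
        if not node.children:
            return frozenset([node.name])
        below = frozenset().union(*(walk(c) for c in node.children))
        if below in (target, other) and node.support is not None:
            found.append(node.support)
        return below

    walk(tree)
    return found[0] if found else None
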