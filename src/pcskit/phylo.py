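"""Distance-based grouping analysis: JTT ML distances, NJ, bootstrap.

Pairwise maximum-likelihood distances under the JTT model (one-dimensional
likelihood optimisation per pair), classical neighbor joining with the
Studier–Keppler Q-criterion and deterministic label-order tie-breaking, and
nonparametric bootstrap supports by site resampling. NJ is exact on
additive distance matrices, which is what the property tests exploit.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize_scalar

from . import jtt

log = logging.getLogger(__name__)

#: distances of saturated pairs are capped here (substitutions/site)
DEFAULT_DISTANCE_CAP = 10.0


@dataclass
class TreeNode:
    """A node of an (un)rooted tree; leaves carry labels, edges lengths."""

    label: str | None = None
    children: list = field(default_factory=list)  # list[(TreeNode, float)]
    support: float | None = None

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaf_labels(self) -> list[str]:
        if self.is_leaf:
            return [self.label]
        out = []
        for child, _ in self.children:
            out.extend(child.leaf_labels())
        return out

    def _newick(self) -> str:
        if self.is_leaf:
            return self.label
        inner = ",".join(
            f"{child._newick()}:{length:.10g}" for child, length in self.children
        )
        sup = "" if self.support is None else f"{self.support:g}"
        return f"({inner}){sup}"

    def to_newick(self) -> str:
        return self._newick() + ";"

    def bipartitions(self) -> set[frozenset]:
        """Non-trivial leaf bipartitions (as the smaller-side frozenset
        complement-normalised against the full leaf set)."""
        full = frozenset(self.leaf_labels())
        parts: set[frozenset] = set()

        def walk(node: TreeNode):
            if node.is_leaf:
                return frozenset([node.label])
            below = frozenset()
            for child, _ in node.children:
                below = below | walk(child)
            if 1 < len(below) < len(full) - 1:
                other = full - below
                parts.add(min(below, other, key=lambda s: (len(s), sorted(s))))
            return below

        walk(self)
        return parts


class DistanceMatrix:
    """Symmetric non-negative labelled distance matrix with zero diagonal."""

    def __init__(self, labels: list[str], matrix: np.ndarray):
        matrix = np.asarray(matrix, dtype=float)
        n = len(labels)
        if matrix.shape != (n, n):
            raise ValueError("matrix shape does not match labels")
        if not np.allclose(matrix, matrix.T, atol=1e-12):
            raise ValueError("matrix must be symmetric")
        if np.abs(np.diag(matrix)).max() > 1e-12:
            raise ValueError("diagonal must be zero")
        if not np.isfinite(matrix).all() or (matrix < 0).any():
            raise ValueError("entries must be finite and non-negative")
        self.labels = list(labels)
        self.matrix = matrix

    def __getitem__(self, pair: tuple[str, str]) -> float:
        i = self.labels.index(pair[0])
        j = self.labels.index(pair[1])
        return float(self.matrix[i, j])


def _pair_counts(seq_a: str, seq_b: str) -> np.ndarray:
    """20x20 site-pattern counts over ungapped, unambiguous columns."""
    if len(seq_a) != len(seq_b):
        raise ValueError("sequences must have equal (aligned) length")
    ia = jtt.encode(seq_a)
    ib = jtt.encode(seq_b)
    keep = (ia >= 0) & (ib >= 0)
    counts = np.zeros((20, 20))
    np.add.at(counts, (ia[keep], ib[keep]), 1.0)
    return counts


def jtt_ml_distance(seq_a: str, seq_b: str,
                    cap: float = DEFAULT_DISTANCE_CAP) -> float:
    """ML divergence (substitutions/site) of an aligned pair under JTT.

    Maximises sum_sites log(pi_a P_ab(t)) by bounded scalar search to 1e-6;
    gap and X columns are dropped pairwise. Saturated pairs are capped.
    """
    counts = _pair_counts(seq_a, seq_b)
    n = counts.sum()
    if n == 0:
        raise ValueError("no overlapping unambiguous sites")
    if np.trace(counts) == n:
        return 0.0
    log_pi = np.log(jtt.equilibrium_frequencies())

    def neg_loglik(t: float) -> float:
        P = jtt.probability_matrix(t)
        with np.errstate(divide="ignore"):
            ll = counts * (log_pi[:, None] + np.log(P))
        return -ll[counts > 0].sum()

    res = minimize_scalar(neg_loglik, bounds=(1e-9, cap), method="bounded",
                          options={"xatol": 1e-6})
    return float(min(res.x, cap))


def distance_matrix(labels: list[str], aligned: list[str],
                    cap: float = DEFAULT_DISTANCE_CAP) -> DistanceMatrix:
    """All pairwise JTT ML distances of an aligned sequence set."""
    n = len(labels)
    mat = np.zeros((n, n))
    for i, j in itertools.combinations(range(n), 2):
        mat[i, j] = mat[j, i] = jtt_ml_distance(aligned[i], aligned[j], cap=cap)
    return DistanceMatrix(labels, mat)


def nj_tree(dm: DistanceMatrix) -> TreeNode:
    """Classical neighbor joining (Saitou–Nei, Studier–Keppler criterion).

    Ties in the Q-criterion break deterministically by label order. Negative
    branch lengths are clamped to 0 (logged). Returns an unrooted tree
    represented with a trifurcating root.
    """
    n = len(dm.labels)
    if n < 3:
        raise ValueError("NJ needs at least 3 taxa")
    nodes: list[TreeNode] = [TreeNode(label=l) for l in dm.labels]
    names: list[str] = list(dm.labels)
    D = dm.matrix.copy()

    def clamp(x: float) -> float:
        if x < 0:
            log.debug("negative branch length %.3g clamped to 0", x)
            return 0.0
        return x

    while len(nodes) > 3:
        m = len(nodes)
        r = D.sum(axis=1)
        best = None
        best_pair = None
        for i in range(m):
            for j in range(i + 1, m):
                q = (m - 2) * D[i, j] - r[i] - r[j]
                key = (q, min(names[i], names[j]), max(names[i], names[j]))
                if best is None or key < best:
                    best = key
                    best_pair = (i, j)
        i, j = best_pair
        vi = clamp(0.5 * D[i, j] + (r[i] - r[j]) / (2.0 * (m - 2)))
        vj = clamp(D[i, j] - (0.5 * D[i, j] + (r[i] - r[j]) / (2.0 * (m - 2))))
        new = TreeNode(children=[(nodes[i], vi), (nodes[j], vj)])
        dnew = 0.5 * (D[i, :] + D[j, :] - D[i, j])
        keep = [k for k in range(m) if k not in (i, j)]
        D2 = np.zeros((m - 1, m - 1))
        D2[:-1, :-1] = D[np.ix_(keep, keep)]
        D2[-1, :-1] = D2[:-1, -1] = dnew[keep]
        nodes = [nodes[k] for k in keep] + [new]
        names = [names[k] for k in keep] + [min(names[i], names[j])]
        D = D2

    # join the final three nodes at a trifurcation (three-point formulas)
    d01, d02, d12 = D[0, 1], D[0, 2], D[1, 2]
    v0 = clamp(0.5 * (d01 + d02 - d12))
    v1 = clamp(0.5 * (d01 + d12 - d02))
    v2 = clamp(0.5 * (d02 + d12 - d01))
    return TreeNode(children=[(nodes[0], v0), (nodes[1], v1), (nodes[2], v2)])


def bootstrap_supports(labels: list[str], aligned: list[str],
                       n_replicates: int = 100, seed: int = 0,
                       cap: float = DEFAULT_DISTANCE_CAP) -> TreeNode:
    """NJ tree with bootstrap supports from site resampling.

    Builds the reference NJ tree on the full alignment, then resamples
    alignment columns with replacement ``n_replicates`` times, rebuilds the
    NJ tree for each replicate and annotates each internal edge of the
    reference tree with the percentage of replicates containing the same
    leaf bipartition. Deterministic for a fixed seed.
    """
    lengths = {len(s) for s in aligned}
    if len(lengths) != 1:
        raise ValueError("bootstrap needs an aligned (equal-length) input")
    (ncol,) = lengths
    ref = nj_tree(distance_matrix(labels, aligned, cap=cap))
    rng = np.random.default_rng(seed)
    counts: dict[frozenset, int] = {bp: 0 for bp in ref.bipartitions()}
    for _ in range(n_replicates):
        cols = rng.integers(0, ncol, size=ncol)
        resampled = ["".join(s[c] for c in cols) for s in aligned]
        rep = nj_tree(distance_matrix(labels, resampled, cap=cap))
        for bp in rep.bipartitions():
            if bp in counts:
                counts[bp] += 1

    def annotate(node: TreeNode, full: frozenset):
        for child, _ in node.children:
            if not child.is_leaf:
                below = frozenset(child.leaf_labels())
                if 1 < len(below) < len(full) - 1:
                    key = min(below, full - below, key=lambda s: (len(s), sorted(s)))
                    child.support = 100.0 * counts[key] / n_replicates
                annotate(child, full)

    annotate(ref, frozenset(ref.leaf_labels()))
    return ref


def support_for_split(tree: TreeNode, side: set[str]) -> float | None:
    """Bootstrap support of the bipartition separating ``side``; None if
    that split is not an edge of the tree."""
    full = frozenset(tree.leaf_labels())
    target = min(frozenset(side), full - frozenset(side),
                 key=lambda s: (len(s), sorted(s)))

    def walk(node: TreeNode) -> float | None:
        for child, _ in node.children:
            if not child.is_leaf:
                below = frozenset(child.leaf_labels())
                key = min(below, full - below, key=lambda s: (len(s), sorted(s)))
                if key == target:
                    return child.support
                found = walk(child)
                if found is not None:
                    return found
        return None

    return walk(tree)
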