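"""Distance trees for TE copies and discordance against the species tree.

Horizontally transferred elements produce TE phylogenies whose topology
contradicts the host species tree.  Trees here are built by neighbor
joining on K2P distances — a fully specified, deterministic construction
(ties broken by the lexicographically smallest label pair) — and compared
with the Robinson-Foulds metric on the shared leaf set: the count of
bipartitions present in exactly one of the two unrooted trees, normalised
by its maximum ``2 (n - 3)`` for binary trees.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import dendropy
import numpy as np
from dendropy.calculate import treecompare

from ._align import global_align
from .divergence import k2p_distance

__all__ = [
    "DistanceMatrixT", "DiscordanceReport", "nj_tree", "rf_distance",
    "te_distance_matrix",
]


@dataclass
class DistanceMatrixT:
    """Symmetric non-negative distance matrix with zero diagonal."""

    labels: list[str]
    matrix: np.ndarray
    saturated: list[tuple[str, str]] = field(default_factory=list)

    def __post_init__(self):
        m = np.asarray(self.matrix, float)
        if m.shape != (len(self.labels), len(self.labels)):
            raise ValueError("matrix shape does not match labels")
        if not np.allclose(m, m.T):
            raise ValueError("distance matrix must be symmetric")
        if (np.diag(m) != 0).any() or (m < 0).any():
            raise ValueError("distances must be non-negative with zero diagonal")
        self.matrix = m


@dataclass(frozen=True)
class DiscordanceReport:
    rf: int
    rf_normalized: float
    shared_leaves: int

    @property
    def discordant(self) -> bool:
        return self.rf > 0


def nj_tree(dm: DistanceMatrixT) -> dendropy.Tree:
    """Neighbor-joining tree (unrooted) from a distance matrix.

    Deterministic: at every agglomeration step ties in the Q criterion are
    broken by the lexicographically smallest (label, label) pair, where a
    cluster is labelled by its smallest member leaf.  Negative branch
    lengths are clamped to zero.
    """
    n0 = len(dm.labels)
    if n0 < 3:
        raise ValueError("neighbor joining needs at least 3 labels")
    D = {i: {j: float(dm.matrix[i, j]) for j in range(n0) if j != i} for i in range(n0)}
    newick = {i: dm.labels[i] for i in range(n0)}
    key = {i: dm.labels[i] for i in range(n0)}
    active = set(range(n0))
    next_id = n0

    def _pairkey(i, j):
        a, b = sorted((key[i], key[j]))
        return (a, b)

    while len(active) > 3:
        n = len(active)
        r = {i: sum(D[i][j] for j in active if j != i) for i in active}
        best = None
        for i in active:
            for j in active:
                if i >= j:
                    continue
                q = (n - 2) * D[i][j] - r[i] - r[j]
                cand = (q, _pairkey(i, j), i, j)
                if best is None or cand[:2] < best[:2]:
                    best = cand
        _, _, i, j = best
        dij = D[i][j]
        li = 0.5 * dij + (r[i] - r[j]) / (2.0 * (n - 2))
        lj = dij - li
        li, lj = max(li, 0.0), max(lj, 0.0)
        new = next_id
        next_id += 1
        D[new] = {}
        for k in active:
            if k in (i, j):
                continue
            dk = 0.5 * (D[i][k] + D[j][k] - dij)
            D[new][k] = D[k][new] = max(dk, 0.0)
        newick[new] = f"({newick[i]}:{li:.10g},{newick[j]}:{lj:.10g})"
        key[new] = min(key[i], key[j])
        active.discard(i)
        active.discard(j)
        active.add(new)

    i, j, k = sorted(active, key=lambda x: key[x])
    li = max(0.5 * (D[i][j] + D[i][k] - D[j][k]), 0.0)
    lj = max(0.5 * (D[i][j] + D[j][k] - D[i][k]), 0.0)
    lk = max(0.5 * (D[i][k] + D[j][k] - D[i][j]), 0.0)
    text = (f"({newick[i]}:{li:.10g},{newick[j]}:{lj:.10g},"
            f"{newick[k]}:{lk:.10g});")
    return dendropy.Tree.get(data=text, schema="newick", preserve_underscores=True)


def _as_newick(tree: "dendropy.Tree | str") -> str:
    if isinstance(tree, dendropy.Tree):
        return tree.as_string(schema="newick", suppress_rooting=True)
    return str(tree)


def rf_distance(tree_a, tree_b) -> DiscordanceReport:
    """Robinson-Foulds distance between two trees pruned to their shared leaves.

    Both trees are treated as unrooted.  Fewer than 4 shared leaves leaves
    topology comparison undefined and raises.
    """
    tns = dendropy.TaxonNamespace()
    ta = dendropy.Tree.get(data=_as_newick(tree_a), schema="newick",
                           taxon_namespace=tns, preserve_underscores=True)
    tb = dendropy.Tree.get(data=_as_newick(tree_b), schema="newick",
                           taxon_namespace=tns, preserve_underscores=True)
    la = {leaf.taxon.label for leaf in ta.leaf_node_iter()}
    lb = {leaf.taxon.label for leaf in tb.leaf_node_iter()}
    shared = sorted(la & lb)
    if len(shared) < 4:
        raise ValueError(
            f"discordance undefined: only {len(shared)} shared leaves (need >= 4)")
    for t, own in ((ta, la), (tb, lb)):
        drop = sorted(own - set(shared))
        if drop:
            t.prune_taxa_with_labels(drop)
        t.is_rooted = False
        t.encode_bipartitions()
    rf = int(treecompare.symmetric_difference(ta, tb))
    max_rf = 2 * (len(shared) - 3)
    return DiscordanceReport(rf, rf / max_rf if max_rf else 0.0, len(shared))


def te_distance_matrix(
    seqs: dict[str, str],
    gap_open: int = -16,
    gap_extend: int = -4,
) -> DistanceMatrixT:
    """Pairwise K2P distances between representative sequences.

    Each pair is globally aligned with the stiff divergence-measurement gap
    scores (the substitution model has no indels, so permissive gaps would
    deflate the distances); saturated
    (undefined) distances are recorded as the maximum defined distance and
    flagged in ``saturated``.
    """
    labels = list(seqs)
    if len(labels) < 3:
        raise ValueError("need at least 3 sequences")
    n = len(labels)
    mat = np.zeros((n, n))
    undef: list[tuple[int, int]] = []
    for i in range(n):
        for j in range(i + 1, n):
            a, b = global_align(seqs[labels[i]], seqs[labels[j]],
                                gap_open=gap_open, gap_extend=gap_extend)
            res = k2p_distance(a, b)
            if res.defined:
                mat[i, j] = mat[j, i] = res.K
            else:
                undef.append((i, j))
    saturated = []
    if undef:
        dmax = float(mat.max())
        for i, j in undef:
            mat[i, j] = mat[j, i] = dmax
            saturated.append((labels[i], labels[j]))
    return DistanceMatrixT(labels, mat, saturated)
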