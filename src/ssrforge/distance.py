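"""Shared-allele distances and neighbor-joining trees.

Individual-level genetic distance is one minus the proportion of alleles
shared across co-typed loci (D_PSA); trees come from canonical
Saitou-Nei neighbor joining with deterministic tie-breaking, and branch
support from bootstrap resampling of loci.  Trees are dendropy objects
throughout, so Newick export and consensus building use its machinery.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

import dendropy
import numpy as np

from .io import GenotypeMatrix

__all__ = [
    "DistanceMatrix",
    "dpsa",
    "dpsa_matrix",
    "neighbor_joining",
    "bootstrap_tree",
]


@dataclass
class DistanceMatrix:
    """Symmetric pairwise distances with a zero diagonal."""

    labels: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != (len(self.labels), len(self.labels)):
            raise ValueError("matrix shape does not match labels")
        if not np.allclose(v, v.T):
            raise ValueError("distance matrix must be symmetric")
        if np.any(np.diag(v) != 0):
            raise ValueError("distance matrix must have a zero diagonal")
        if np.any(v < 0):
            raise ValueError("distances must be non-negative")
        self.values = v

    def get(self, a: str, b: str) -> float:
        return float(self.values[self.labels.index(a), self.labels.index(b)])


def dpsa(
    matrix: GenotypeMatrix, ind_a: str, ind_b: str, loci: list[str] | None = None
) -> float:
    """Shared-allele distance between two diploid individuals.

    D = 1 - (sum of per-locus allele matches) / (2 * L), where matches at a
    locus count each allele at most once (0, 1 or 2) and L is the number of
    loci typed in both individuals.  Values are multiples of 1/(2L).
    """
    loci = loci if loci is not None else matrix.loci
    shared = 0
    co_typed = 0
    for locus in loci:
        ca, cb = matrix.call(ind_a, locus), matrix.call(ind_b, locus)
        if ca is None or cb is None:
            continue
        co_typed += 1
        shared += sum((Counter(ca) & Counter(cb)).values())
    if co_typed == 0:
        raise ValueError(f"no co-typed loci between {ind_a!r} and {ind_b!r}")
    return 1.0 - shared / (2.0 * co_typed)


def dpsa_matrix(matrix: GenotypeMatrix, loci: list[str] | None = None) -> DistanceMatrix:
    labels = list(matrix.individuals)
    n = len(labels)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = dpsa(matrix, labels[i], labels[j], loci)
    return DistanceMatrix(labels, d)


# ---------------------------------------------------------------------------
# Neighbor joining


def neighbor_joining(
    matrix: DistanceMatrix, taxon_namespace: dendropy.TaxonNamespace | None = None
) -> dendropy.Tree:
    """Canonical Saitou-Nei neighbor joining.

    At each step the pair minimizing Q_ij = (N-2) d_ij - r_i - r_j is
    joined; ties break on the lexicographically smallest pair of subtree
    labels, making the output fully deterministic.  Negative branch
    lengths are clamped to zero for display, with the raw value kept in
    the edge annotation ``raw_length``.  On an additive matrix the tree's
    path lengths reproduce the input exactly.
    """
    n = len(matrix.labels)
    if n < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")
    tns = taxon_namespace or dendropy.TaxonNamespace(matrix.labels)
    nodes: dict[int, dendropy.Node] = {}
    minlabel: dict[int, str] = {}
    for i, label in enumerate(matrix.labels):
        node = dendropy.Node(taxon=tns.get_taxon(label))
        nodes[i] = node
        minlabel[i] = label
    d: dict[frozenset[int], float] = {}
    for i in range(n):
        for j in range(i + 1, n):
            d[frozenset((i, j))] = float(matrix.values[i, j])

    def _set_edge(node: dendropy.Node, length: float) -> None:
        node.edge.length = max(length, 0.0)
        node.edge.annotations["raw_length"] = length

    active = list(range(n))
    next_id = n
    while len(active) > 3:
        big_n = len(active)
        r = {i: sum(d[frozenset((i, k))] for k in active if k != i) for i in active}
        best = None
        for ai in range(big_n):
            for aj in range(ai + 1, big_n):
                i, j = active[ai], active[aj]
                q = (big_n - 2) * d[frozenset((i, j))] - r[i] - r[j]
                tie = tuple(sorted((minlabel[i], minlabel[j])))
                key = (q, tie)
                if best is None or key < best[0]:
                    best = (key, i, j)
        _, i, j = best
        dij = d[frozenset((i, j))]
        li = dij / 2.0 + (r[i] - r[j]) / (2.0 * (big_n - 2))
        lj = dij - li
        parent = dendropy.Node()
        parent.add_child(nodes[i])
        parent.add_child(nodes[j])
        _set_edge(nodes[i], li)
        _set_edge(nodes[j], lj)
        u = next_id
        next_id += 1
        nodes[u] = parent
        minlabel[u] = min(minlabel[i], minlabel[j])
        for k in active:
            if k in (i, j):
                continue
            d[frozenset((u, k))] = (
                d[frozenset((i, k))] + d[frozenset((j, k))] - dij
            ) / 2.0
        active = [k for k in active if k not in (i, j)] + [u]

    a, b, c = active
    center = dendropy.Node()
    dab, dac, dbc = (
        d[frozenset((a, b))],
        d[frozenset((a, c))],
        d[frozenset((b, c))],
    )
    for node_id, length in (
        (a, (dab + dac - dbc) / 2.0),
        (b, (dab + dbc - dac) / 2.0),
        (c, (dac + dbc - dab) / 2.0),
    ):
        center.add_child(nodes[node_id])
        _set_edge(nodes[node_id], length)

    tree = dendropy.Tree(taxon_namespace=tns, seed_node=center)
    tree.is_rooted = False
    return tree


# ---------------------------------------------------------------------------
# Bootstrap support


def _internal_splits(tree: dendropy.Tree) -> set[int]:
    tree.encode_bipartitions()
    n_leaves = len(tree.taxon_namespace)
    splits = set()
    for edge in tree.preorder_edge_iter():
        if edge.head_node.is_leaf() or edge.head_node is tree.seed_node:
            continue
        bp = edge.bipartition
        if 1 <= bin(bp.split_bitmask).count("1") <= n_leaves - 1:
            splits.add(bp.split_bitmask)
    return splits


def bootstrap_tree(
    matrix: GenotypeMatrix,
    n_reps: int = 1000,
    seed: int = 0,
) -> tuple[dendropy.Tree, dendropy.Tree]:
    """Full-data NJ tree with bootstrap supports, plus the majority-rule
    consensus of the replicates.

    Each replicate resamples loci with replacement (same count), recomputes
    D_PSA and the NJ tree; the support of each internal edge of the
    full-data tree is the percentage of replicates containing the same
    bipartition, written as the internal node label.
    """
    if len(matrix.individuals) < 3:
        raise ValueError("need at least 3 individuals")
    if len(matrix.loci) < 2:
        raise ValueError("bootstrap over loci needs at least 2 loci")
    rng = np.random.default_rng(seed)
    tns = dendropy.TaxonNamespace(matrix.individuals)
    full = neighbor_joining(dpsa_matrix(matrix), taxon_namespace=tns)

    replicate_trees = dendropy.TreeList(taxon_namespace=tns)
    split_counts: Counter[int] = Counter()
    for _ in range(n_reps):
        loci = [matrix.loci[k] for k in rng.integers(0, len(matrix.loci), len(matrix.loci))]
        rep = neighbor_joining(dpsa_matrix(matrix, loci), taxon_namespace=tns)
        split_counts.update(_internal_splits(rep))
        replicate_trees.append(rep)

    full.encode_bipartitions()
    for node in full.preorder_node_iter():
        if node.is_leaf() or node is full.seed_node:
            continue
        pct = 100.0 * split_counts[node.edge.bipartition.split_bitmask] / n_reps
        node.label = str(int(round(pct)))

    consensus = replicate_trees.consensus(min_freq=0.5)
    return full, consensus


def support_for_clade(tree: dendropy.Tree, taxa: set[str]) -> float | None:
    """Bootstrap support (%) recorded on the edge splitting ``taxa`` from
    the rest, or None when the tree has no such edge."""
    tree.encode_bipartitions()
    target = frozenset(taxa)
    all_taxa = {t.label for t in tree.taxon_namespace}
    for node in tree.preorder_node_iter():
        if node.is_leaf() or node is tree.seed_node or node.label is None:
            continue
        leaves = {l.taxon.label for l in node.leaf_iter()}
        if leaves == target or leaves == all_taxa - target:
            return float(node.label)
    return None
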