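import numpy as np
import pytest

from ssrforge import GenotypeMatrix, PopulationSpec, SimulationSpec


@pytest.fixture
def small_matrix():
    """4 individuals, 2 loci, one missing call."""
    calls = {
        ("s1", "L1"): (100, 102), ("s1", "L2"): (200, 200),
        ("s2", "L1"): (100, 104), ("s2", "L2"): (200, 202),
        ("s3", "L1"): (102, 102), ("s3", "L2"): None,
        ("s4", "L1"): (100, 100), ("s4", "L2"): (202, 202),
    }
    return GenotypeMatrix(["s1", "s2", "s3", "s4"], ["L1", "L2"], calls,
                          ["P1", "P1", "P2", "P2"])


def three_population_spec(seed=7, n_per_pop=10, n_loci=12):
    """Three populations with disjoint allele pools (4 alleles each)."""
    pops = []
    for name, off in (("P1", 0), ("P2", 20), ("P3", 40)):
        freqs = {
            f"L{l:02d}": {100 + off + 2 * a: 0.25 for a in range(4)}
            for l in range(n_loci)
        }
        pops.append(PopulationSpec(name, n_per_pop, freqs))
    return SimulationSpec(seed=seed, populations=pops)


# ---------------------------------------------------------------------------
# Random additive trees and an exhaustive least-squares NJ oracle


def _enumerate_topologies(n):
    """All unrooted binary topologies on leaves 0..n-1 as edge lists."""
    base = [(0, n), (1, n), (2, n)]  # 3-leaf star, internal ids start at n
    trees = [(base, n + 1)]
    for leaf in range(3, n):
        new_trees = []
        for edges, next_int in trees:
            for k, (u, v) in enumerate(edges):
                split = edges[:k] + edges[k + 1:]
                split += [(u, next_int), (v, next_int), (leaf, next_int)]
                new_trees.append((split, next_int + 1))
        trees = new_trees
    return [edges for edges, _ in trees]


def _paths(edges, n):
    """Leaf-pair -> ordered list of edge indices, via adjacency walk."""
    adj = {}
    for idx, (u, v) in enumerate(edges):
        adj.setdefault(u, []).append((v, idx))
        adj.setdefault(v, []).append((u, idx))
    out = {}
    for a in range(n):
        # BFS from leaf a
        prev = {a: (None, None)}
        queue = [a]
        while queue:
            x = queue.pop()
            for y, idx in adj[x]:
                if y not in prev:
                    prev[y] = (x, idx)
                    queue.append(y)
        for b in range(a + 1, n):
            path = []
            node = b
            while node != a:
                node, idx = prev[node]
                path.append(idx)
            out[(a, b)] = path
    return out


def topology_bipartitions(edges, n):
    """Canonical bipartition set: for each internal edge, the leaf side not
    containing leaf 0."""
    adj = {}
    for u, v in edges:
        adj.setdefault(u, set()).add(v)
        adj.setdefault(v, set()).add(u)

    def leaves_below(child, parent):
        found = set()
        stack = [(child, parent)]
        while stack:
            x, p = stack.pop()
            if x < n:
                found.add(x)
            for y in adj[x]:
                if y != p:
                    stack.append((y, x))
        return found

    bips = set()
    for u, v in edges:
        if u >= n and v >= n:  # internal edge
            side = leaves_below(u, v)
            if 0 in side:
                side = set(range(n)) - side
            if 2 <= len(side) <= n - 2:
                bips.add(frozenset(side))
    return bips


def ls_oracle_topology(dist, n):
    """Exhaustive search: the topology whose least-squares branch-length fit
    minimizes the residual to the distance matrix."""
    best = None
    for edges in _enumerate_topologies(n):
        paths = _paths(edges, n)
        pairs = sorted(paths)
        A = np.zeros((len(pairs), len(edges)))
        y = np.array([dist[a, b] for a, b in pairs])
        for r, pair in enumerate(pairs):
            A[r, paths[pair]] = 1.0
        sol, *_ = np.linalg.lstsq(A, y, rcond=None)
        sse = float(np.sum((A @ sol - y) ** 2))
        if best is None or sse < best[0]:
            best = (sse, edges)
    return topology_bipartitions(best[1], n), best[0]


def random_additive_tree(rng, n):
    """Random binary topology with positive branch lengths; returns
    (bipartition set, exact path-distance matrix)."""
    edges = [(0, n), (1, n), (2, n)]
    next_int = n + 1
    for leaf in range(3, n):
        k = int(rng.integers(0, len(edges)))
        u, v = edges.pop(k)
        edges += [(u, next_int), (v, next_int), (leaf, next_int)]
        next_int += 1
    lengths = rng.uniform(0.5, 3.0, size=len(edges))
    paths = _paths(edges, n)
    dist = np.zeros((n, n))
    for (a, b), path in paths.items():
        dist[a, b] = dist[b, a] = lengths[path].sum()
    return topology_bipartitions(edges, n), dist


def nj_bipartitions(tree, labels):
    """Bipartitions of an ssrforge NJ tree in the oracle's canonical form."""
    index = {label: i for i, label in enumerate(labels)}
    n = len(labels)
    bips = set()
    tree.encode_bipartitions()
    for node in tree.preorder_node_iter():
        if node.is_leaf() or node is tree.seed_node:
            continue
        side = {index[l.taxon.label] for l in node.leaf_iter()}
        if 0 in side:
            side = set(range(n)) - side
        if 2 <= len(side) <= n - 2:
            bips.add(frozenset(side))
    return bips
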