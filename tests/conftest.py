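"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import numpy as np
import pytest

from dicelineage.genome import GenomeLayout
from dicelineage.profiles import CopyNumberProfile
from dicelineage.tree import CellLineageTree, TreeNode


# ---------------------------------------------------------------------------
# small genome layouts


@pytest.fixture
def tiny_layout() -> GenomeLayout:
    """Two chromosomes, 5 and 3 bins of 1 Mbp."""
    return GenomeLayout(
        chromosomes=(("chr1", 5_000_000), ("chr2", 3_000_000)),
        bin_size=1_000_000,
        region_size=1_000,
    )


def make_profile(layout, values, cell_id="cell", allele_mode="total"):
    """Profile from a dict {(chrom, allele): list} or a flat per-chrom dict."""
    data = {}
    for key, vec in values.items():
        if isinstance(key, str):
            key = (key, 0)
        data[key] = np.asarray(vec, dtype=np.int64)
    return CopyNumberProfile(cell_id, layout, data, allele_mode)


def random_profiles(layout, n_cells, rng, allele_mode="total", max_cn=6):
    out = []
    n_alleles = 1 if allele_mode == "total" else 2
    for i in range(n_cells):
        data = {
            (chrom, a): rng.integers(0, max_cn + 1, size=layout.n_bins(chrom))
            for chrom in layout.chrom_names
            for a in range(n_alleles)
        }
        out.append(CopyNumberProfile(f"cell_{i}", layout, data, allele_mode))
    return out


# ---------------------------------------------------------------------------
# independent tree oracles (adjacency-based, separate from the search code)


def enumerate_topologies(n):
    """All unrooted binary topologies on taxa 0..n-1, by edge insertion."""
    trees = [({n: [0, 1, 2], 0: [n], 1: [n], 2: [n]}, n + 1)]
    for t in range(3, n):
        nxt_gen = []
        for adj, nxt in trees:
            edges = [(u, v) for u in adj for v in adj[u] if u < v]
            for u, v in edges:
                a = {k: list(vs) for k, vs in adj.items()}
                w = nxt
                a[u][a[u].index(v)] = w
                a[v][a[v].index(u)] = w
                a[w] = [u, v, t]
                a[t] = [w]
                nxt_gen.append((a, nxt + 1))
        trees = nxt_gen
    return [adj for adj, _ in trees]


def random_topology(n, rng):
    """One random unrooted binary topology on taxa 0..n-1."""
    adj = {n: [0, 1, 2], 0: [n], 1: [n], 2: [n]}
    nxt = n + 1
    for t in range(3, n):
        edges = [(u, v) for u in adj for v in adj[u] if u < v]
        u, v = edges[rng.integers(len(edges))]
        w = nxt
        nxt += 1
        adj[u][adj[u].index(v)] = w
        adj[v][adj[v].index(u)] = w
        adj[w] = [u, v, t]
        adj[t] = [w]
    return adj


def adjacency_to_tree(adj, ids) -> CellLineageTree:
    """Convert an adjacency oracle tree to a CellLineageTree."""
    n_taxa = len(ids)
    root = next(k for k in adj if len(adj[k]) == 3)

    def build(node, came):
        tn = TreeNode(name=str(ids[node]) if node < n_taxa else None)
        for nb in adj[node]:
            if nb != came:
                tn.add(build(nb, node))
        return tn

    return CellLineageTree(build(root, None))


def additive_matrix(adj, n, rng=None, lengths=None):
    """Path-sum distance matrix over an adjacency topology.

    Branch lengths are random in [0.2, 2] unless given; returns (D, lengths).
    """
    if lengths is None:
        lengths = {}
        for u in adj:
            for v in adj[u]:
                if (v, u) not in lengths:
                    lengths[(u, v)] = lengths[(v, u)] = float(rng.uniform(0.2, 2.0))
    D = np.zeros((n, n))
    for i in range(n):
        dist = {i: 0.0}
        stack = [i]
        while stack:
            u = stack.pop()
            for nb in adj[u]:
                if nb not in dist:
                    dist[nb] = dist[u] + lengths[(u, nb)]
                    stack.append(nb)
        for j in range(n):
            D[i, j] = dist[j]
    return D, lengths


def random_symmetric_matrix(n, rng, scale=5.0):
    X = rng.uniform(0, scale, size=(n, n))
    D = (X + X.T) / 2
    np.fill_diagonal(D, 0.0)
    return D
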