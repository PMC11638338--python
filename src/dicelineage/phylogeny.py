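"""Distance-based reconstruction of cell lineage trees.

Two reconstruction engines operate on a symmetric cell-by-cell distance
matrix:

* :func:`neighbor_joining` — the classical Saitou–Nei agglomeration,
  kept as a baseline.
* :func:`bme_tree` — balanced minimum evolution: the tree minimising the
  Pauplin length ``L(T) = Σ_{i<j} 2^(1-p_ij) D_ij`` where ``p_ij`` is the
  topological (edge-count) leaf-to-leaf path length.  The search builds an
  initial tree by greedy sequential taxon insertion and then hill-climbs
  with subtree-prune-and-regraft (SPR) moves.

The search never evaluates the length functional naively.  For a subtree
``S`` rooted at a node, define the balanced average distance
``Δ(S1, S2) = Σ_{i∈S1, j∈S2} 2^(-d1(i)) 2^(-d2(j)) D_ij`` with ``d`` the
edge-depth of a leaf inside its subtree.  Attaching a piece ``P`` onto an
edge ``e`` that splits the remainder into sides ``A`` and ``B`` changes
the length by

    phi(e) = [Δ(P, A) + Δ(P, B) - Δ(A, B)] / 2        (up to a constant),

so candidate placements are ranked by ``phi`` alone.  All Δ terms reduce
to entries of two matrices computed per tree in O(n²): ``M[u, v]`` =
Δ between the clades below ``u`` and ``v``, and ``MU[u, v]`` = Δ between
the complement of ``u``'s clade and the clade below ``v``.  Tests assert
that this incremental scoring agrees exactly with the naive evaluation of
the length functional.
"""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np

from .distances import DICE_STAR, DistanceVariant, distance_matrix
from .tree import CellLineageTree, TreeNode

__all__ = [
    "neighbor_joining",
    "balanced_length",
    "bme_tree",
    "infer_lineage",
]


def _check_matrix(D: np.ndarray) -> np.ndarray:
    D = np.asarray(D, dtype=float)
    if D.ndim != 2 or D.shape[0] != D.shape[1]:
        raise ValueError("distance matrix must be square")
    if D.shape[0] < 3:
        raise ValueError("need at least 3 taxa")
    if not np.allclose(D, D.T):
        raise ValueError("distance matrix must be symmetric")
    if np.any(D < 0):
        raise ValueError("distances must be non-negative")
    return D


# ---------------------------------------------------------------------------
# neighbor joining


def neighbor_joining(ids: Sequence[str], D: np.ndarray) -> CellLineageTree:
    """Saitou–Nei neighbor joining.

    Deterministic: when several pairs minimise the Q criterion the pair
    with the lowest (row, column) index is joined.  Returns an unrooted
    binary tree (root of degree 3); negative branch-length estimates are
    clamped to zero.
    """
    D = _check_matrix(D)
    n = len(ids)
    if n != D.shape[0]:
        raise ValueError("ids and matrix size differ")

    size = 2 * n
    M = np.zeros((size, size))
    M[:n, :n] = D
    nodes: list[Optional[TreeNode]] = [TreeNode(name=str(i)) for i in ids] + [
        None
    ] * n
    active = list(range(n))
    nxt = n

    while len(active) > 3:
        m = len(active)
        idx = np.array(active)
        sub = M[np.ix_(idx, idx)]
        r = sub.sum(axis=1)
        Q = (m - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(Q, np.inf)
        i_, j_ = divmod(int(np.argmin(Q)), m)  # row-major => lowest index pair
        if i_ > j_:
            i_, j_ = j_, i_
        a, b = int(idx[i_]), int(idx[j_])
        la = 0.5 * M[a, b] + (r[i_] - r[j_]) / (2 * (m - 2))
        lb = M[a, b] - la
        na, nb = nodes[a], nodes[b]
        na.length = max(float(la), 0.0)
        nb.length = max(float(lb), 0.0)
        nodes[nxt] = TreeNode(children=[na, nb])
        for c in active:
            if c != a and c != b:
                M[nxt, c] = M[c, nxt] = 0.5 * (M[a, c] + M[b, c] - M[a, b])
        active = [c for c in active if c != a and c != b] + [nxt]
        nxt += 1

    a, b, c = active
    root = TreeNode()
    for x, y, z in ((a, b, c), (b, a, c), (c, a, b)):
        nodes[x].length = max(0.5 * (M[x, y] + M[x, z] - M[y, z]), 0.0)
        root.add(nodes[x])
    return CellLineageTree(root)


# ---------------------------------------------------------------------------
# balanced length (naive definition; reference implementation)


def _unrooted_adjacency(tree: CellLineageTree):
    """Adjacency of the unrooted topology; a degree-2 root is suppressed.

    Returns ``(adj, leaf_of_node)`` with integer node ids.
    """
    adj: dict[int, list[int]] = {}
    leaf_name: dict[int, str] = {}
    counter = [0]

    def visit(node: TreeNode) -> int:
        nid = counter[0]
        counter[0] += 1
        adj[nid] = []
        if node.is_leaf:
            leaf_name[nid] = node.name
        for child in node.children:
            cid = visit(child)
            adj[nid].append(cid)
            adj[cid].append(nid)
        return nid

    root_id = visit(tree.root)
    if len(adj[root_id]) == 2:  # rooted representation of an unrooted tree
        u, v = adj[root_id]
        adj[u].remove(root_id)
        adj[v].remove(root_id)
        adj[u].append(v)
        adj[v].append(u)
        del adj[root_id]
    return adj, leaf_name


def balanced_length(tree: CellLineageTree, ids: Sequence[str], D: np.ndarray) -> float:
    """Pauplin (balanced) length of ``tree`` under matrix ``D``.

    Direct evaluation of ``Σ_{i<j} 2^(1-p_ij) D_ij`` with ``p_ij`` found by
    breadth-first search; requires an unrooted-binary topology whose leaves
    are exactly ``ids``.  On a matrix additive over the tree this equals
    the sum of the branch lengths.
    """
    D = np.asarray(D, dtype=float)
    adj, leaf_name = _unrooted_adjacency(tree)
    if sorted(leaf_name.values()) != sorted(str(i) for i in ids):
        raise ValueError("tree leaves do not match matrix ids")
    for nid, nbrs in adj.items():
        if nid not in leaf_name and len(nbrs) != 3:
            raise ValueError("balanced length requires a binary unrooted tree")
    index = {str(name): i for i, name in enumerate(ids)}

    total = 0.0
    leaf_ids = sorted(leaf_name)
    for src in leaf_ids:
        dist = {src: 0}
        queue = [src]
        while queue:
            u = queue.pop()
            for nb in adj[u]:
                if nb not in dist:
                    dist[nb] = dist[u] + 1
                    queue.append(nb)
        i = index[leaf_name[src]]
        for dst in leaf_ids:
            if dst <= src:
                continue
            j = index[leaf_name[dst]]
            total += 2.0 ** (1 - dist[dst]) * D[i, j]
    return total


# ---------------------------------------------------------------------------
# balanced minimum evolution search


def _orient(adj: dict[int, list[int]], root: int):
    """BFS orientation: (order, parent, children); parent[root] = -1."""
    parent = {root: -1}
    order = [root]
    i = 0
    while i < len(order):
        u = order[i]
        i += 1
        for nb in adj[u]:
            if nb != parent[u]:
                parent[nb] = u
                order.append(nb)
    children = {u: [nb for nb in adj[u] if nb != parent[u]] for u in order}
    return order, parent, children


def _avg_matrices(order, parent, children, root, D, size):
    """Balanced average-distance matrices for the current topology.

    ``M[u, x]`` is Δ(clade(u), clade(x)) (valid for disjoint clades);
    ``MU[u, x]`` is Δ(complement of clade(u), clade(x)) (valid for
    ``x`` inside clade(u) or disjoint from the complement's hole).
    Leaf node ids coincide with taxon indices of ``D``.
    """
    M = np.zeros((size, size))
    leaves = np.array([v for v in order if not children[v]])
    M[np.ix_(leaves, leaves)] = D[np.ix_(leaves, leaves)]
    internal_post = [v for v in reversed(order) if children[v] and v != root]
    for v in internal_post:
        c1, c2 = children[v]
        M[:, v] = 0.5 * (M[:, c1] + M[:, c2])
    for v in internal_post:
        c1, c2 = children[v]
        M[v, :] = 0.5 * (M[c1, :] + M[c2, :])

    MU = np.zeros((size, size))
    r0, r1, r2 = children[root]
    MU[r0, :] = 0.5 * (M[r1, :] + M[r2, :])
    MU[r1, :] = 0.5 * (M[r0, :] + M[r2, :])
    MU[r2, :] = 0.5 * (M[r0, :] + M[r1, :])
    for v in order:
        p = parent[v]
        if p == -1 or p == root:
            continue
        c1, c2 = children[p]
        sib = c2 if c1 == v else c1
        MU[v, :] = 0.5 * (MU[p, :] + M[sib, :])
    return M, MU


def _tree_length(order, children, root, M) -> float:
    """Balanced length from the average-distance matrix (O(n))."""
    acc = {v: 0.0 for v in order}
    for v in reversed(order):
        ch = children[v]
        if ch and v != root:
            c1, c2 = ch
            acc[v] = acc[c1] + acc[c2] + 0.5 * M[c1, c2]
    r0, r1, r2 = children[root]
    return (
        acc[r0]
        + acc[r1]
        + acc[r2]
        + 0.5 * (M[r0, r1] + M[r0, r2] + M[r1, r2])
    )


def _greedy_build(D: np.ndarray, taxa_order: Sequence[int]):
    """Sequential insertion minimising the balanced length at each step.

    Returns the adjacency of the unrooted binary tree; leaf node ids are
    taxon indices, internal ids start at ``n``; node ``n`` (the first hub)
    is always internal and serves as the orientation root.
    """
    n = D.shape[0]
    size = 2 * n
    hub = n
    a, b, c = taxa_order[:3]
    adj: dict[int, list[int]] = {hub: [a, b, c], a: [hub], b: [hub], c: [hub]}
    nxt = n + 1

    for t in taxa_order[3:]:
        order, parent, children = _orient(adj, hub)
        M, MU = _avg_matrices(order, parent, children, hub, D, size)
        dv = D[t]
        dd = np.zeros(size)
        du = np.zeros(size)
        for v in reversed(order):
            ch = children[v]
            if not ch:
                dd[v] = dv[v]
            elif v != hub:
                dd[v] = 0.5 * (dd[ch[0]] + dd[ch[1]])
        r0, r1, r2 = children[hub]
        for v in order[1:]:
            p = parent[v]
            if p == hub:
                o = [x for x in (r0, r1, r2) if x != v]
                du[v] = 0.5 * (dd[o[0]] + dd[o[1]])
            else:
                c1, c2 = children[p]
                sib = c2 if c1 == v else c1
                du[v] = 0.5 * (du[p] + dd[sib])

        best_v, best_phi = None, np.inf
        for v in order[1:]:  # edge (parent[v], v); earliest edge wins ties
            phi = 0.5 * (dd[v] + du[v] - MU[v, v])
            if phi < best_phi:
                best_phi, best_v = phi, v
        p = parent[best_v]
        w = nxt
        nxt += 1
        adj[p][adj[p].index(best_v)] = w
        adj[best_v][adj[best_v].index(p)] = w
        adj[w] = [p, best_v, t]
        adj[t] = [w]
    return adj, hub


def _best_spr_move(adj, D, root, size, first_improvement, tol):
    """Scan all (pruned subtree, regraft edge) pairs; return the best move.

    Returns ``(delta_L, move)`` where ``move = (q, p_nb, w, x)``: detach
    node ``q`` (keeping its neighbour ``p_nb`` on the pruned side), join
    ``q``'s two other neighbours, and re-splice ``q`` into edge ``(w, x)``.
    ``delta_L`` is the exact change in balanced length (negative = better).
    """
    order, parent, children = _orient(adj, root)
    M_np, MU_np = _avg_matrices(order, parent, children, root, D, size)
    M = M_np.tolist()
    MU = MU_np.tolist()

    def delta(p1, p2):
        k1, n1 = p1
        k2, n2 = p2
        if k1 == 0:
            return M[n1][n2] if k2 == 0 else MU[n2][n1]
        return MU[n1][n2]  # up-up pairs never occur in valid walks

    best_dl, best_move = -tol, None

    for v in order[1:]:
        candidates = [((0, v), parent[v], v)]  # prune clade(v), q = parent
        if children[v]:
            candidates.append(((1, v), v, parent[v]))  # prune complement
        for P, q, p_nb in candidates:
            sides = []
            for nb in adj[q]:
                if nb == p_nb:
                    continue
                piece = (0, nb) if parent.get(nb) == q else (1, q)
                sides.append((nb, piece))
            if len(sides) != 2:
                continue
            (nb1, pc1), (nb2, pc2) = sides
            phi_restore = 0.5 * (delta(P, pc1) + delta(P, pc2) - delta(pc1, pc2))

            for (start_nb, _), (_, other_pc) in ((sides[0], sides[1]), (sides[1], sides[0])):
                G = other_pc
                stack = [(start_nb, q, delta(P, other_pc), 1)]
                while stack:
                    w, came, dPA, d = stack.pop()
                    nbrs = [x for x in adj[w] if x != came]
                    if not nbrs:
                        continue
                    x1, x2 = nbrs
                    half = 2.0 ** (-(d + 1))
                    for x, xo in ((x1, x2), (x2, x1)):
                        if parent.get(x) == w:
                            X, U = (0, x), (1, x)
                        else:
                            X, U = (1, w), (0, w)
                        Xo = (0, xo) if parent.get(xo) == w else (1, w)
                        dPX = delta(P, X)
                        dPA_edge = 0.5 * (dPA + delta(P, Xo))
                        dAX = delta(U, X) + half * (delta(G, X) - dPX)
                        dl = 0.5 * (dPX + dPA_edge - dAX) - phi_restore
                        if dl < best_dl:
                            best_dl, best_move = dl, (q, p_nb, w, x)
                            if first_improvement:
                                return best_dl, best_move
                        stack.append((x, w, dPA_edge, d + 1))
    return best_dl, best_move


def _balanced_length_adj(adj, root, D, size) -> float:
    order, parent, children = _orient(adj, root)
    M, _ = _avg_matrices(order, parent, children, root, D, size)
    return _tree_length(order, children, root, M)


def _tree_to_adjacency(tree: CellLineageTree, ids: Sequence[str]):
    """Adjacency of an unrooted binary tree with leaf ids mapped to taxon
    indices; internal ids start at ``n`` with the orientation root at ``n``."""
    index = {str(name): i for i, name in enumerate(ids)}
    n = len(ids)
    uadj, leaf_name = _unrooted_adjacency(tree)
    internal = [v for v in uadj if v not in leaf_name]
    remap = {}
    for v in leaf_name:
        remap[v] = index[leaf_name[v]]
    for k, v in enumerate(internal):
        remap[v] = n + k
    adj = {remap[u]: [remap[v] for v in nbrs] for u, nbrs in uadj.items()}
    return adj, n


def _apply_spr(adj, move) -> None:
    q, p_nb, w, x = move
    b_, c_ = [nb for nb in adj[q] if nb != p_nb]
    adj[q] = [p_nb]
    adj[b_][adj[b_].index(q)] = c_
    adj[c_][adj[c_].index(q)] = b_
    adj[w][adj[w].index(x)] = q
    adj[x][adj[x].index(w)] = q
    adj[q].extend([w, x])


def _branch_lengths(adj, root, D, size):
    """Balanced least-squares edge lengths, keyed by the child node of each
    oriented edge; negative estimates are clamped to zero."""
    order, parent, children = _orient(adj, root)
    M, MU = _avg_matrices(order, parent, children, root, D, size)

    def delta(p1, p2):
        k1, n1 = p1
        k2, n2 = p2
        if k1 == 0:
            return M[n1, n2] if k2 == 0 else MU[n2, n1]
        if k2 == 0:
            return MU[n1, n2]
        raise AssertionError("up-up pair")

    def sides_at(node, excluding):
        out = []
        for nb in adj[node]:
            if nb == excluding:
                continue
            out.append((0, nb) if parent.get(nb) == node else (1, node))
        return out

    lengths = {}
    for v in order[1:]:
        p = parent[v]
        A, B = sides_at(p, v)
        if not children[v]:  # external edge to leaf v
            val = 0.5 * (delta((0, v), A) + delta((0, v), B) - delta(A, B))
        else:
            C = (0, children[v][0])
            Dside = (0, children[v][1])
            val = 0.25 * (
                delta(A, C) + delta(A, Dside) + delta(B, C) + delta(B, Dside)
            ) - 0.5 * (delta(A, B) + delta(C, Dside))
        lengths[v] = max(float(val), 0.0)
    return lengths


def _adjacency_to_tree(adj, root, ids, lengths=None) -> CellLineageTree:
    n_taxa = len(ids)

    def build(node, came) -> TreeNode:
        tn = TreeNode(name=str(ids[node]) if node < n_taxa else None)
        if lengths is not None and came is not None:
            tn.length = lengths.get(node)
        for nb in adj[node]:
            if nb != came:
                tn.add(build(nb, node))
        return tn

    return CellLineageTree(build(root, None))


def bme_tree(
    ids: Sequence[str],
    D: np.ndarray,
    do_spr: bool = True,
    first_improvement: bool = False,
    seed: Optional[int] = None,
    max_sweeps: int = 10_000,
) -> CellLineageTree:
    """Balanced-minimum-evolution tree for distance matrix ``D``.

    The initial tree is grown by greedy sequential insertion (taxa in
    input order, or a seeded random order when ``seed`` is given); if the
    NJ topology scores lower it is used as the starting point instead, so
    the search never ends worse than NJ under its own criterion.  With
    ``do_spr`` the topology is then improved by repeated SPR moves,
    accepting the move with the greatest decrease in balanced length
    (``first_improvement=True`` accepts the first improving move instead)
    until no move improves.  Ties are broken toward the earliest candidate
    in a fixed traversal order, so the result is deterministic.
    """
    D = _check_matrix(D)
    n = len(ids)
    if n != D.shape[0]:
        raise ValueError("ids and matrix size differ")
    taxa_order = list(range(n))
    if seed is not None:
        rng = np.random.default_rng(seed)
        taxa_order = list(rng.permutation(n))

    size = 2 * n
    adj, root = _greedy_build(D, taxa_order)
    if n > 3:
        # start the search from the better of the greedy-insertion tree and
        # the NJ topology, so the final tree never scores worse than NJ
        # under the balanced criterion
        nj_adj, nj_root = _tree_to_adjacency(neighbor_joining(ids, D), ids)
        if _balanced_length_adj(nj_adj, nj_root, D, size) < _balanced_length_adj(
            adj, root, D, size
        ):
            adj, root = nj_adj, nj_root

    if do_spr and n > 3:
        tol = 1e-11 * (1.0 + float(np.abs(D).sum()))
        for _ in range(max_sweeps):
            dl, move = _best_spr_move(adj, D, root, size, first_improvement, tol)
            if move is None:
                break
            _apply_spr(adj, move)

    lengths = _branch_lengths(adj, root, D, size)
    return _adjacency_to_tree(adj, root, ids, lengths)


def infer_lineage(
    profiles,
    variant: DistanceVariant = DICE_STAR,
    method: str = "balme",
    do_spr: bool = True,
    seed: Optional[int] = None,
) -> CellLineageTree:
    """Distance matrix + tree method, composed.

    ``method`` is ``"balme"`` (balanced minimum evolution with SPR, the
    engine behind both the standard-root and breakpoint-root pipelines) or
    ``"nj"`` (neighbor joining).
    """
    ids, D = distance_matrix(profiles, variant)
    if method == "balme":
        return bme_tree(ids, D, do_spr=do_spr, seed=seed)
    if method == "nj":
        return neighbor_joining(ids, D)
    raise ValueError(f"unknown method {method!r}")
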