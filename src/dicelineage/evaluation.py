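"""Metrics comparing inferred cell lineage trees with ground truth.

All tree metrics are topology-only and treat trees as unrooted:

* :func:`nrfd` — normalized Robinson–Foulds distance over nontrivial
  bipartitions.
* :func:`clone_f1` — for each ground-truth clone, the best F1 over all
  bipartition sides of the tree, averaged over clones.
* :func:`breakpoint_precision_recall` — informative-breakpoint agreement
  between clean and noisy copy-number profiles.
* :func:`clade_induced_ari` — adjusted Rand index between externally
  inferred clusters and the best-matching clades of the tree.
* :func:`sibling_dissimilarity` — mean normalized Hamming distance
  between the profiles of leaf siblings (cherries).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
from sklearn.metrics import adjusted_rand_score

from .profiles import CloneAssignment, CopyNumberProfile
from .tree import CellLineageTree, TreeNode


@dataclass
class EvalReport:
    """Bundle of evaluation results for one tree/truth pair."""

    nrfd: Optional[float] = None
    clone_f1: Optional[float] = None
    precision: Optional[float] = None
    recall: Optional[float] = None
    ari: Optional[float] = None
    sibling_dissimilarity: Optional[float] = None
    altered: Optional[float] = None

    def to_dict(self) -> dict:
        return {k: v for k, v in self.__dict__.items() if v is not None}


# ---------------------------------------------------------------------------
# Robinson–Foulds


def nrfd(t1: CellLineageTree, t2: CellLineageTree) -> float:
    """Normalized Robinson–Foulds distance between two unrooted trees.

    The symmetric difference of the nontrivial bipartition sets divided by
    the total number of nontrivial bipartitions in the two trees, so that
    0 means identical topologies and 1 maximally different.  Multifurcating
    trees simply assert fewer bipartitions: a star tree against a binary
    tree scores 1, and an unresolved tree is penalised only for the splits
    it actually asserts.
    """
    if set(t1.leaf_names()) != set(t2.leaf_names()):
        raise ValueError("trees must share an identical leaf set")
    b1 = t1.bipartitions()
    b2 = t2.bipartitions()
    denom = len(b1) + len(b2)
    if denom == 0:
        return 0.0
    return len(b1 ^ b2) / denom


# ---------------------------------------------------------------------------
# clone detection F1


def _bipartition_sides(tree: CellLineageTree) -> list[frozenset[str]]:
    """Both sides of every nontrivial bipartition of the unrooted tree."""
    all_leaves = frozenset(tree.leaf_names())
    sides: set[frozenset[str]] = set()
    for split in tree.bipartitions():
        sides.add(split)
        sides.add(all_leaves - split)
    return sorted(sides, key=lambda s: (len(s), sorted(s)))


def _f1(pred: frozenset, truth: set) -> float:
    inter = len(pred & truth)
    if inter == 0:
        return 0.0
    return 2 * inter / (len(pred) + len(truth))


def clone_f1(tree: CellLineageTree, clones: CloneAssignment) -> float:
    """Mean over clones of the best F1 over all bipartition sides.

    Treating one side of a nontrivial unrooted bipartition as the
    predicted members of a clone, each ground-truth clone picks the side
    maximising its F1; the score is the average over clones.  1.0 means
    every clone is exactly a clade side of the tree.
    """
    leaves = set(tree.leaf_names())
    clone_sets = clones.clones()
    if not clone_sets:
        raise ValueError("no clones to evaluate")
    for label, members in clone_sets.items():
        if not members:
            raise ValueError(f"clone {label!r} is empty")
        if not members <= leaves:
            raise ValueError(f"clone {label!r} contains cells missing from the tree")
    sides = _bipartition_sides(tree)
    return float(
        np.mean(
            [max(_f1(side, members) for side in sides) for members in clone_sets.values()]
        )
    )


# ---------------------------------------------------------------------------
# breakpoint precision/recall


def _informative_indices(profile: CopyNumberProfile) -> dict:
    return {
        key: set(np.nonzero(np.diff(vec))[0].tolist())
        for key, vec in profile.data.items()
    }


def breakpoint_counts(
    clean: CopyNumberProfile, noisy: CopyNumberProfile
) -> tuple[int, int, int]:
    """(TP, FP, FN) of informative breakpoints, pooled over chromosomes.

    Per chromosome/allele, the informative sets are
    ``X = {i : b_i != 0}`` from the clean profile and ``X'`` from the
    noisy one; TP = |X ∩ X'|, FP = |X' − X|, FN = |X − X'|.
    """
    if not clean.same_layout(noisy):
        raise ValueError("clean and noisy profiles have mismatched layouts")
    xc = _informative_indices(clean)
    xn = _informative_indices(noisy)
    tp = fp = fn = 0
    for key in xc:
        tp += len(xc[key] & xn[key])
        fp += len(xn[key] - xc[key])
        fn += len(xc[key] - xn[key])
    return tp, fp, fn


def breakpoint_precision_recall(
    clean, noisy
) -> tuple[float, float]:
    """Pooled precision and recall of breakpoint detection.

    Accepts a single profile pair or two equal-length profile lists (the
    dataset-level call); counts are pooled over chromosomes and cells
    before the ratios.  Empty denominators (no positives possible) score
    1.0 — with nothing to find or nothing found, no errors were made.
    """
    if isinstance(clean, CopyNumberProfile):
        clean, noisy = [clean], [noisy]
    clean, noisy = list(clean), list(noisy)
    if len(clean) != len(noisy):
        raise ValueError("clean and noisy lists differ in length")
    tp = fp = fn = 0
    for c, n in zip(clean, noisy):
        a, b, d = breakpoint_counts(c, n)
        tp, fp, fn = tp + a, fp + b, fn + d
    precision = tp / (tp + fp) if (tp + fp) else 1.0
    recall = tp / (tp + fn) if (tp + fn) else 1.0
    return precision, recall


def altered_bin_fraction(clean, noisy) -> float:
    """Fraction of (cell, bin) entries whose copy number changed."""
    if isinstance(clean, CopyNumberProfile):
        clean, noisy = [clean], [noisy]
    altered = total = 0
    for c, n in zip(clean, noisy):
        if not c.same_layout(n):
            raise ValueError("clean and noisy profiles have mismatched layouts")
        for key in c.keys():
            altered += int((c.data[key] != n.data[key]).sum())
            total += len(c.data[key])
    return altered / total


# ---------------------------------------------------------------------------
# clade-induced ARI


def _copy_tree(node: TreeNode) -> TreeNode:
    out = TreeNode(name=node.name)
    out.children = [_copy_tree(c) for c in node.children]
    return out


def _clades_of(root: TreeNode) -> list[tuple[TreeNode, frozenset[str]]]:
    out = []

    def visit(node: TreeNode) -> frozenset[str]:
        if not node.children:
            s = frozenset((node.name,))
        else:
            s = frozenset().union(*(visit(c) for c in node.children))
        out.append((node, s))
        return s

    visit(root)
    return out


def _prune(root: TreeNode, target: TreeNode) -> Optional[TreeNode]:
    """Remove the clade at ``target``; collapse empty/unary internals."""
    if root is target:
        return None

    def visit(node: TreeNode) -> Optional[TreeNode]:
        node.children = [
            kept
            for c in node.children
            if c is not target and (kept := visit(c)) is not None
        ]
        if not node.children and node.name is None:
            return None
        if len(node.children) == 1 and node.name is None:
            return node.children[0]
        return node

    return visit(root)


def clade_induced_ari(
    tree: CellLineageTree, clusters: CloneAssignment, max_clusters: int = 8
) -> float:
    """Concordance between a tree's clades and an external clustering.

    For each ordering of the clusters: repeatedly pick, for the next
    cluster, the clade of the (progressively pruned) tree with maximum F1
    against the cluster's remaining cells, label that clade's leaves with
    the cluster, prune it, and continue.  The adjusted Rand index between
    the induced labels and the input clusters (over all leaves; cells
    missing from either labelling form their own group) is maximised over
    all orderings.  Invariant to relabelling of the clusters.
    """
    cluster_sets = clusters.clones()
    if not cluster_sets:
        raise ValueError("no clusters to evaluate")
    if len(cluster_sets) > max_clusters:
        raise ValueError(
            f"{len(cluster_sets)} clusters exceed the ordering-enumeration limit "
            f"({max_clusters}); coarsen the clustering or raise max_clusters"
        )
    leaves = tree.leaf_names()
    if not set(clusters.cells()) <= set(leaves):
        raise ValueError("clustered cells missing from the tree")

    best = -1.0
    for ordering in itertools.permutations(sorted(cluster_sets)):
        root = _copy_tree(tree.root)
        induced: dict[str, str] = {}
        for label in ordering:
            if root is None:
                break
            members = cluster_sets[label]
            clades = _clades_of(root)
            node, _ = max(
                clades,
                key=lambda kv: (_f1(kv[1], members), -len(kv[1])),
            )
            chosen = next(s for nd, s in clades if nd is node)
            for cell in chosen:
                induced[cell] = label
            root = _prune(root, node)
        a = [clusters.labels.get(cell, "__none__") for cell in leaves]
        b = [induced.get(cell, "__unassigned__") for cell in leaves]
        best = max(best, float(adjusted_rand_score(a, b)))
    return best


# ---------------------------------------------------------------------------
# sibling dissimilarity


def sibling_dissimilarity(
    tree: CellLineageTree, profiles: Iterable[CopyNumberProfile]
) -> float:
    """Mean normalized Hamming distance between cherry (sibling) profiles.

    Over all leaf pairs sharing a parent, the fraction of bins with
    unequal copy number, averaged over pairs.  Low values mean adjacent
    cells in the tree carry similar genomes.
    """
    by_cell = {p.cell_id: p for p in profiles}
    cherries = tree.cherries()
    if not cherries:
        raise ValueError("tree has no cherries")
    vals = []
    for a, b in cherries:
        if a not in by_cell or b not in by_cell:
            raise ValueError(f"missing profile for cherry ({a!r}, {b!r})")
        va, vb = by_cell[a].vector(), by_cell[b].vector()
        vals.append(float((va != vb).mean()))
    return float(np.mean(vals))
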