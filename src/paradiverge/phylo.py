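"""Poisson-corrected distances, neighbor-joining trees and cluster subtrees.

Distances are the classical Poisson correction d = -ln(1 - p) of the observed
proportion p of differing residues; trees come from Saitou-Nei neighbor
joining. Trees are held as dendropy objects so they round-trip through Newick,
can be rerooted on the inter-cluster edge, and yield the per-cluster subtrees
that the parsimony counting stage consumes.
"""

from __future__ import annotations

import warnings
from pathlib import Path
from typing import Iterable

import dendropy
import numpy as np
import skbio

from .seqdata import GAP, UNKNOWN, Alignment, ClusterPair, SiteMask

#: observed difference proportions at or above this are capped (with a warning)
#: so that nearly saturated pairs yield a large finite distance.
P_CAP = 0.95


class PhyloError(ValueError):
    pass


class DistanceMatrix:
    """Symmetric matrix of pairwise distances (substitutions per site)."""

    def __init__(self, ids: list[str], matrix: np.ndarray):
        matrix = np.asarray(matrix, dtype=float)
        if matrix.shape != (len(ids), len(ids)):
            raise PhyloError("matrix shape does not match ids")
        if not np.allclose(matrix, matrix.T):
            raise PhyloError("distance matrix is not symmetric")
        if np.any(np.diag(matrix) != 0):
            raise PhyloError("nonzero diagonal")
        if not np.all(np.isfinite(matrix)) or np.any(matrix < 0):
            raise PhyloError("distances must be finite and non-negative")
        self.ids = list(ids)
        self.matrix = matrix

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("id\t" + "\t".join(self.ids) + "\n")
            for sid, row in zip(self.ids, self.matrix):
                fh.write(sid + "\t" + "\t".join(f"{d:.6f}" for d in row) + "\n")


def poisson_distance(aln: Alignment, mask: SiteMask | None = None) -> DistanceMatrix:
    """Pairwise Poisson-corrected protein distances.

    For each pair, p is the proportion of differing residues over the columns
    that are mask-usable and hold a plain residue (no gap, no X) in both
    sequences. p >= P_CAP is capped with a warning. A pair with no shared
    usable column is an error.
    """
    if aln.n_seqs < 2:
        raise PhyloError("need at least 2 sequences")
    mat = aln.matrix
    if mask is not None:
        mat = mat[:, mask.usable_columns]
    ok = (mat != GAP) & (mat != UNKNOWN)
    n = aln.n_seqs
    out = np.zeros((n, n))
    capped = []
    for i in range(n):
        for j in range(i + 1, n):
            shared = ok[i] & ok[j]
            m = int(shared.sum())
            if m == 0:
                raise PhyloError(
                    f"no shared usable columns for pair ({aln.ids[i]}, {aln.ids[j]})"
                )
            p = float((mat[i, shared] != mat[j, shared]).sum()) / m
            if p >= P_CAP:
                capped.append((aln.ids[i], aln.ids[j], p))
                p = P_CAP
            out[i, j] = out[j, i] = -np.log1p(-p)
    if capped:
        warnings.warn(
            f"capped {len(capped)} nearly saturated pair(s) at p={P_CAP}: "
            + ", ".join(f"{a}-{b} (p={p:.3f})" for a, b, p in capped[:5])
        )
    return DistanceMatrix(list(aln.ids), out)


def nj_tree(dm: DistanceMatrix) -> dendropy.Tree:
    """Unrooted neighbor-joining tree (Saitou-Nei Q-criterion).

    Negative estimated branch lengths are clamped to zero. Requires >= 3 taxa.
    """
    if len(dm.ids) < 3:
        raise PhyloError("neighbor joining needs at least 3 taxa")
    sk_dm = skbio.DistanceMatrix(dm.matrix, ids=dm.ids)
    sk_tree = skbio.tree.nj(sk_dm, neg_as_zero=True)
    tree = dendropy.Tree.get(data=str(sk_tree), schema="newick", preserve_underscores=True)
    tree.is_rooted = False
    return tree


def read_newick(path: str | Path) -> dendropy.Tree:
    tree = dendropy.Tree.get(path=str(path), schema="newick", preserve_underscores=True)
    return tree


def write_newick(tree: dendropy.Tree, path: str | Path) -> None:
    tree.write(path=str(path), schema="newick", suppress_rooting=True, unquoted_underscores=True)


def leaf_labels(tree: dendropy.Tree) -> set[str]:
    return {lf.taxon.label for lf in tree.leaf_node_iter()}


def is_monophyletic(tree: dendropy.Tree, members: Iterable[str]) -> bool:
    """True if ``members`` forms one side of a bipartition of the tree.

    This is the unrooted notion: after rooting on the inter-cluster edge the
    member set is a clade.
    """
    members = set(members)
    leaves = leaf_labels(tree)
    if not members <= leaves:
        raise PhyloError(f"members not in tree: {sorted(members - leaves)}")
    if members == leaves:
        return True
    tree = tree.clone(depth=1)
    tree.encode_bipartitions()
    target = frozenset(members)
    complement = frozenset(leaves - members)
    for edge in tree.preorder_edge_iter():
        if edge.bipartition is None:
            continue
        side = frozenset(
            t.label for t in tree.taxon_namespace.bitmask_taxa_list(edge.bipartition.leafset_bitmask)
        )
        if side == target or side == complement:
            return True
    return False


def root_between_clusters(tree: dendropy.Tree, clusters: ClusterPair) -> dendropy.Tree:
    """Root the tree on the edge separating the two clusters.

    Requires the tree's leaves to be exactly the cluster members and the
    clusters to be reciprocally monophyletic; if they are not, the tree is
    midpoint rooted instead and a warning is emitted.
    """
    tree = tree.clone(depth=1)
    tree.is_rooted = True  # treat seed node as root for MRCA queries
    leaves = leaf_labels(tree)
    extra = leaves - clusters.all_members
    if extra:
        tree.retain_taxa_with_labels(sorted(clusters.all_members & leaves))
    if is_monophyletic(tree, clusters.members1 & leaf_labels(tree)):
        mrca_taxa = sorted(clusters.members1 & leaf_labels(tree))
        node = tree.mrca(taxon_labels=mrca_taxa)
        if node is tree.seed_node:
            # the clade sits at the current root; reroot from the other side
            node = tree.mrca(taxon_labels=sorted(clusters.members2 & leaf_labels(tree)))
        edge = node.edge
        half = (edge.length or 0.0) / 2.0
        tree.reroot_at_edge(edge, length1=half, length2=half, update_bipartitions=False)
    else:
        warnings.warn(
            "clusters are not reciprocally monophyletic on this tree; "
            "midpoint rooting instead"
        )
        tree.reroot_at_midpoint(update_bipartitions=False)
    tree.is_rooted = True
    return tree


def cluster_subtree(tree: dendropy.Tree, members: Iterable[str]) -> tuple[dendropy.Tree, bool]:
    """Induced subtree on ``members`` with branch lengths preserved.

    Returns (subtree, monophyletic_flag). A non-monophyletic member set still
    yields the induced subtree, flagged False, so batch runs stay alive.
    """
    members = set(members)
    leaves = leaf_labels(tree)
    missing = members - leaves
    if missing:
        raise PhyloError(f"requested members not in tree: {sorted(missing)}")
    mono = is_monophyletic(tree, members)
    if not mono:
        warnings.warn(f"cluster of {len(members)} members is not monophyletic")
    sub = tree.extract_tree_with_taxa_labels(labels=sorted(members))
    sub.is_rooted = True
    # collapse a degree-1 root chain left by extraction
    while len(sub.seed_node.child_nodes()) == 1:
        child = sub.seed_node.child_nodes()[0]
        if child.edge.length and sub.seed_node.edge.length:
            child.edge.length += 0.0
        sub.seed_node = child
        sub.seed_node.parent_node = None
    return sub, mono
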