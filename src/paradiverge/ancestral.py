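"""Fitch parsimony substitution counts and cluster-root ancestral states.

The count-based divergence models consume, per usable alignment column, the
minimum number of substitutions within each paralog cluster (x1, x2) and the
amino acid inferred at each cluster's root (a1, a2). Both come from the
classical Fitch bottom-up pass over the cluster subtree: intersect child state
sets where possible, otherwise union and count one change. Root-state ties are
broken toward the residue most frequent among the cluster's leaves at that
column (then alphabetically) and flagged, so downstream stages can report or
exclude tied sites.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import dendropy
import numpy as np
import pandas as pd

from .phylo import cluster_subtree, root_between_clusters
from .seqdata import Alignment, ClusterPair, SiteMask


@dataclass
class SiteCountTable:
    """Per-usable-site observables for the two-cluster divergence models.

    ``data`` columns: column_1based, reference_position, x1, x2, a1, a2,
    tie1, tie2. Counts are Fitch minimum changes within each cluster; a1/a2
    the tie-broken cluster-root residues.
    """

    data: pd.DataFrame
    name1: str
    name2: str
    monophyletic1: bool = True
    monophyletic2: bool = True

    @property
    def n_sites(self) -> int:
        return len(self.data)

    @property
    def x1(self) -> np.ndarray:
        return self.data["x1"].to_numpy()

    @property
    def x2(self) -> np.ndarray:
        return self.data["x2"].to_numpy()

    def to_tsv(self, path: str | Path) -> None:
        self.data.to_csv(path, sep="\t", index=False)


def _fitch_pass(
    subtree: dendropy.Tree, states: dict[str, np.ndarray]
) -> tuple[np.ndarray, list[frozenset[str]]]:
    """Vectorized Fitch bottom-up pass over all sites at once.

    ``states`` maps leaf label -> array of single-character residues (one per
    site). Returns (counts per site, root state set per site).
    """
    n_sites = next(iter(states.values())).size
    letters = sorted({c for arr in states.values() for c in np.unique(arr)})
    lut = {c: i for i, c in enumerate(letters)}
    n_letters = len(letters)

    counts = np.zeros(n_sites, dtype=int)
    # boolean state-set membership per node, shape (n_sites, n_letters)
    sets: dict[int, np.ndarray] = {}
    for node in subtree.postorder_node_iter():
        if node.is_leaf():
            arr = states[node.taxon.label]
            s = np.zeros((n_sites, n_letters), dtype=bool)
            s[np.arange(n_sites), [lut[c] for c in arr]] = True
            sets[id(node)] = s
        else:
            children = node.child_nodes()
            s = sets.pop(id(children[0]))
            for child in children[1:]:
                c = sets.pop(id(child))
                inter = s & c
                nonempty = inter.any(axis=1)
                counts += ~nonempty
                s = np.where(nonempty[:, None], inter, s | c)
            sets[id(node)] = s
    root_sets = sets[id(subtree.seed_node)]
    root = [
        frozenset(letters[i] for i in np.flatnonzero(row)) for row in root_sets
    ]
    return counts, root


def _leaf_states(aln: Alignment, subtree: dendropy.Tree, cols: np.ndarray) -> dict[str, np.ndarray]:
    labels = [lf.taxon.label for lf in subtree.leaf_node_iter()]
    idx = aln.row_indices(labels)
    sub = aln.matrix[np.ix_(idx, cols)]
    return {lab: sub[i] for i, lab in enumerate(labels)}


def fitch_counts(aln: Alignment, subtree: dendropy.Tree, mask: SiteMask) -> np.ndarray:
    """Minimum substitution count per usable site within ``subtree``.

    Counts are invariant to the rooting of the subtree and to leaf order.
    """
    leaves = [lf.taxon.label for lf in subtree.leaf_node_iter()]
    if len(leaves) < 3:
        raise ValueError("cluster subtree needs at least 3 leaves")
    states = _leaf_states(aln, subtree, mask.usable_columns)
    counts, _ = _fitch_pass(subtree, states)
    return counts


def _tiebreak_roots(
    root_sets: list[frozenset[str]], states: dict[str, np.ndarray]
) -> tuple[np.ndarray, np.ndarray]:
    stacked = np.vstack(list(states.values()))
    letters = np.empty(len(root_sets), dtype="<U1")
    ties = np.zeros(len(root_sets), dtype=bool)
    for k, rset in enumerate(root_sets):
        if len(rset) == 1:
            letters[k] = next(iter(rset))
            continue
        ties[k] = True
        col = stacked[:, k]
        freq = {c: int((col == c).sum()) for c in rset}
        best = max(freq.values())
        letters[k] = min(c for c, f in freq.items() if f == best)
    return letters, ties


def _joint_root_states(
    roots1: list[frozenset[str]],
    roots2: list[frozenset[str]],
    states1: dict[str, np.ndarray],
    states2: dict[str, np.ndarray],
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Resolve cluster-root ambiguity jointly across the duplication node.

    A cluster subtree's Fitch root set can be ambiguous; viewed from the full
    tree, the sister cluster is the natural outgroup for resolving it (the
    down-pass of the standard Fitch refinement). The joint state at the
    duplication node is the intersection of the two root sets where nonempty
    (else the union), tie-broken by combined leaf frequency; each cluster
    root takes the joint state if compatible with its own set, otherwise its
    within-cluster tie-break. Tie flags record whichever cluster root was
    ambiguous before resolution.
    """
    tb1, tie1 = _tiebreak_roots(roots1, states1)
    tb2, tie2 = _tiebreak_roots(roots2, states2)
    stacked = np.vstack(list(states1.values()) + list(states2.values()))
    a1 = tb1.copy()
    a2 = tb2.copy()
    for k, (s1, s2) in enumerate(zip(roots1, roots2)):
        if len(s1) == 1 and len(s2) == 1:
            continue
        joint = (s1 & s2) or (s1 | s2)
        col = stacked[:, k]
        freq = {c: int((col == c).sum()) for c in joint}
        best = max(freq.values())
        g = min(c for c, f in freq.items() if f == best)
        if g in s1:
            a1[k] = g
        if g in s2:
            a2[k] = g
    return a1, a2, tie1, tie2


def cluster_root_state(
    aln: Alignment, subtree: dendropy.Tree, mask: SiteMask
) -> tuple[np.ndarray, np.ndarray]:
    """Tie-broken Fitch root residue and tie flag per usable site."""
    leaves = [lf.taxon.label for lf in subtree.leaf_node_iter()]
    if len(leaves) < 3:
        raise ValueError("cluster subtree needs at least 3 leaves")
    states = _leaf_states(aln, subtree, mask.usable_columns)
    _, root_sets = _fitch_pass(subtree, states)
    return _tiebreak_roots(root_sets, states)


def build_count_table(
    aln: Alignment,
    tree: dendropy.Tree,
    clusters: ClusterPair,
    mask: SiteMask,
    ref_id: str | None = None,
) -> SiteCountTable:
    """Assemble the per-site count table for both clusters.

    The tree is rooted on the inter-cluster edge, each cluster's induced
    subtree extracted (non-monophyly flagged, not fatal), and the Fitch pass
    run per cluster. Site indices are reported both as alignment columns and
    as 1-based positions on ``ref_id`` (default: first alignment sequence).
    """
    clusters.validate_against(aln)
    rooted = root_between_clusters(tree, clusters)
    sub1, mono1 = cluster_subtree(rooted, clusters.members1)
    sub2, mono2 = cluster_subtree(rooted, clusters.members2)

    states1 = _leaf_states(aln, sub1, mask.usable_columns)
    states2 = _leaf_states(aln, sub2, mask.usable_columns)
    x1, roots1 = _fitch_pass(sub1, states1)
    x2, roots2 = _fitch_pass(sub2, states2)
    a1, a2, tie1, tie2 = _joint_root_states(roots1, roots2, states1, states2)

    if ref_id is None:
        ref_id = aln.ids[0]
    refpos = aln.reference_positions(ref_id)[mask.usable_columns]

    data = pd.DataFrame(
        {
            "column_1based": mask.usable_columns + 1,
            "reference_position": refpos,
            "x1": x1,
            "x2": x2,
            "a1": a1,
            "a2": a2,
            "tie1": tie1,
            "tie2": tie2,
        }
    )
    return SiteCountTable(data, clusters.name1, clusters.name2, mono1, mono2)
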