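"""Protein alignments, paralog cluster assignments and site masks.

This module handles the plumbing shared by every downstream stage: reading a
multiple protein alignment, validating a two-cluster (duplicate gene pair)
assignment against it, deciding which columns are usable for count-based
divergence analysis (complete deletion with respect to cluster members), and
column bootstrapping.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

AA_LETTERS = "ACDEFGHIKLMNPQRSTVWY"
GAP = "-"
UNKNOWN = "X"
ALPHABET = frozenset(AA_LETTERS) | {GAP, UNKNOWN}


class AlignmentError(ValueError):
    """Raised when an input alignment violates a structural invariant."""


@dataclass
class Alignment:
    """A validated protein multiple alignment.

    Parameters
    ----------
    ids
        Ordered, unique sequence identifiers.
    rows
        One residue string per id, all the same length, drawn from the 20
        amino-acid letters plus ``-`` (gap) and ``X`` (unknown).
    """

    ids: list[str]
    rows: list[str]
    _matrix: np.ndarray = field(init=False, repr=False)
    _index: dict[str, int] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        if len(self.ids) != len(self.rows):
            raise AlignmentError("ids and rows differ in length")
        if not self.ids:
            raise AlignmentError("empty alignment")
        if len(set(self.ids)) != len(self.ids):
            dupes = sorted({i for i in self.ids if self.ids.count(i) > 1})
            raise AlignmentError(f"duplicate sequence ids: {dupes}")
        self.rows = [r.upper() for r in self.rows]
        length = len(self.rows[0])
        if length == 0:
            raise AlignmentError(f"zero-length sequence: {self.ids[0]!r}")
        for sid, row in zip(self.ids, self.rows):
            if len(row) != length:
                raise AlignmentError(
                    f"ragged alignment: {sid!r} has length {len(row)}, "
                    f"expected {length}"
                )
            bad = set(row) - ALPHABET
            if bad:
                raise AlignmentError(
                    f"sequence {sid!r} contains characters outside the "
                    f"amino-acid alphabet: {sorted(bad)}"
                )
        self._matrix = np.array([list(r) for r in self.rows], dtype="<U1")
        self._index = {sid: i for i, sid in enumerate(self.ids)}

    @property
    def n_seqs(self) -> int:
        return len(self.ids)

    @property
    def length(self) -> int:
        return self._matrix.shape[1]

    @property
    def matrix(self) -> np.ndarray:
        """Residues as an (n_seqs, length) array of single characters."""
        return self._matrix

    def row(self, sid: str) -> str:
        return self.rows[self._index[sid]]

    def row_indices(self, ids: Iterable[str]) -> np.ndarray:
        missing = [i for i in ids if i not in self._index]
        if missing:
            raise AlignmentError(f"ids not in alignment: {missing}")
        return np.array([self._index[i] for i in ids], dtype=int)

    def column(self, k: int) -> np.ndarray:
        return self._matrix[:, k]

    def take_columns(self, cols: Sequence[int]) -> "Alignment":
        sub = self._matrix[:, list(cols)]
        return Alignment(list(self.ids), ["".join(r) for r in sub])

    def reference_positions(self, ref_id: str) -> np.ndarray:
        """1-based ungapped positions of ``ref_id`` per column (0 where gapped)."""
        row = np.array(list(self.row(ref_id)))
        pos = np.cumsum(row != GAP)
        pos[row == GAP] = 0
        return pos.astype(int)


@dataclass
class ClusterPair:
    """Two disjoint taxon sets defining the paralog clusters."""

    name1: str
    name2: str
    members1: frozenset[str]
    members2: frozenset[str]

    def __post_init__(self) -> None:
        self.members1 = frozenset(self.members1)
        self.members2 = frozenset(self.members2)
        if self.members1 & self.members2:
            raise ValueError(
                f"clusters overlap: {sorted(self.members1 & self.members2)}"
            )
        for name, members in ((self.name1, self.members1), (self.name2, self.members2)):
            if len(members) < 3:
                raise ValueError(
                    f"cluster {name!r} has {len(members)} members; at least 3 "
                    "are needed for within-cluster substitution counting"
                )

    @property
    def all_members(self) -> frozenset[str]:
        return self.members1 | self.members2

    def validate_against(self, aln: Alignment) -> None:
        missing = sorted(self.all_members - set(aln.ids))
        if missing:
            raise AlignmentError(f"cluster members absent from alignment: {missing}")


@dataclass
class SiteMask:
    """Per-column usability flags (complete deletion over cluster members)."""

    usable: np.ndarray  # bool, length L
    reason: list[str]  # "" | "gap" | "unknown"

    def __post_init__(self) -> None:
        self.usable = np.asarray(self.usable, dtype=bool)
        if len(self.reason) != self.usable.size:
            raise ValueError("mask reason list length mismatch")

    @property
    def n_usable(self) -> int:
        return int(self.usable.sum())

    @property
    def usable_columns(self) -> np.ndarray:
        return np.flatnonzero(self.usable)

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("column_1based\tusable\treason\n")
            for k, (u, r) in enumerate(zip(self.usable, self.reason), start=1):
                fh.write(f"{k}\t{int(u)}\t{r}\n")


def read_alignment(path: str | Path) -> Alignment:
    """Read and validate an aligned FASTA file.

    Lowercase residues are uppercased. Ragged records, duplicate ids, empty
    files and non-standard letters (``U``, ``O``, ``B``, ``Z``, ``J``...) are
    rejected with an explicit error.
    """
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise AlignmentError(f"no FASTA records found in {path}")
    return Alignment([r.id for r in records], [str(r.seq) for r in records])


def write_alignment(aln: Alignment, path: str | Path) -> None:
    records = [
        SeqRecord(Seq(row), id=sid, description="")
        for sid, row in zip(aln.ids, aln.rows)
    ]
    SeqIO.write(records, str(path), "fasta")


def read_clusters(path: str | Path) -> ClusterPair:
    """Read a two-column TSV (sequence_id, cluster_label) into a ClusterPair.

    The file must contain exactly two distinct labels; the lexicographically
    smaller label becomes cluster 1.
    """
    pairs: list[tuple[str, str]] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 2:
                raise ValueError(f"expected two tab-separated columns, got: {line!r}")
            pairs.append((fields[0], fields[1]))
    labels = sorted({lab for _, lab in pairs})
    if len(labels) != 2:
        raise ValueError(f"expected exactly two cluster labels, got {labels}")
    lab1, lab2 = labels
    members1 = frozenset(s for s, lab in pairs if lab == lab1)
    members2 = frozenset(s for s, lab in pairs if lab == lab2)
    return ClusterPair(lab1, lab2, members1, members2)


def build_site_mask(aln: Alignment, clusters: ClusterPair) -> SiteMask:
    """Flag columns usable for divergence analysis.

    A column is usable iff no cluster member carries a gap or an unknown
    residue there. Gaps confined to non-member sequences (outgroups) do not
    exclude a column. Raises if no column survives.
    """
    clusters.validate_against(aln)
    idx = aln.row_indices(sorted(clusters.all_members))
    sub = aln.matrix[idx, :]
    has_gap = (sub == GAP).any(axis=0)
    has_unknown = (sub == UNKNOWN).any(axis=0)
    usable = ~(has_gap | has_unknown)
    reason = [
        "gap" if g else ("unknown" if x else "")
        for g, x in zip(has_gap, has_unknown)
    ]
    mask = SiteMask(usable, reason)
    if mask.n_usable == 0:
        raise AlignmentError("no usable columns after complete deletion")
    return mask


def bootstrap_columns(aln: Alignment, n_reps: int, seed: int) -> list[Alignment]:
    """Draw ``n_reps`` column-bootstrap replicates of the alignment.

    Each replicate has the original number of columns drawn with replacement;
    replicate sequences are reproducible for a given seed.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    rng = np.random.default_rng(seed)
    reps = []
    for _ in range(n_reps):
        cols = rng.integers(0, aln.length, size=aln.length)
        reps.append(aln.take_columns(cols))
    return reps
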