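"""Divergent-site calling, conservation summaries and enrichment testing.

The downstream consumer of the fitted models: threshold the site posteriors
(the conventional cutoff Q > 0.67 corresponds to a posterior ratio R > 2),
summarize per-cluster conservation at chosen sites, verify the type-II
pattern (high conservation in both clusters plus a radical modal change), and
test whether called sites are enriched in a list of drug-binding residues
with a chi-square (or Fisher exact) test on the 2x2 table.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import chi2, fisher_exact

from .seqdata import GAP, UNKNOWN, Alignment, ClusterPair
from .type1_model import SitePosteriorProfile
from .type2_model import AAGroupScheme, DEFAULT_SCHEME, classify_change


@dataclass
class BindingSiteList:
    """Drug-binding residues as 1-based positions on a named reference."""

    reference: str
    positions: list[int]
    letters: list[str]
    label: str = ""

    def __post_init__(self) -> None:
        if len(self.positions) != len(self.letters):
            raise ValueError("positions and letters differ in length")
        if len(set(self.positions)) != len(self.positions):
            raise ValueError("duplicate binding-site positions")
        if any(p < 1 for p in self.positions):
            raise ValueError("positions are 1-based; got a value < 1")

    def validate_against(self, aln: Alignment) -> None:
        """Check each stated residue letter against the reference sequence."""
        ref = self.reference
        ungapped = "".join(c for c in aln.row(ref) if c not in (GAP, UNKNOWN))
        for pos, letter in zip(self.positions, self.letters):
            if pos > len(ungapped):
                raise ValueError(
                    f"position {pos} beyond reference length {len(ungapped)}"
                )
            actual = ungapped[pos - 1]
            if actual != letter.upper():
                raise ValueError(
                    f"binding site {letter}{pos}: reference {ref!r} has "
                    f"{actual!r} at position {pos} — coordinate mismatch?"
                )


def read_binding_sites(path: str | Path, reference: str, label: str = "") -> BindingSiteList:
    """Read a TSV of (position, residue_letter[, label]) rows."""
    positions, letters = [], []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            positions.append(int(fields[0]))
            letters.append(fields[1].upper())
            if len(fields) > 2 and not label:
                label = fields[2]
    return BindingSiteList(reference, positions, letters, label)


@dataclass
class EnrichmentResult:
    """Chi-square / Fisher enrichment of divergent sites among binding sites."""

    table: tuple[int, int, int, int]  # (div&bind, div&!bind, !div&bind, !div&!bind)
    chi2_stat: float
    p_chi2: float
    p_fisher: float
    odds_ratio: float
    method: str
    small_expected: bool = False

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2, default=float)

    @property
    def p_value(self) -> float:
        return self.p_chi2 if self.method == "chi-square" else self.p_fisher


def call_divergent_sites(
    profile: SitePosteriorProfile, cutoff: float = 0.67
) -> pd.DataFrame:
    """Sites with posterior Q(k) strictly above ``cutoff``.

    Returns a frame of (reference_position, Q, R) sorted by position. The
    equivalent posterior-ratio form of the default cutoff is R > ~2.
    """
    if not (0.0 < cutoff < 1.0):
        raise ValueError(f"cutoff must be in (0, 1), got {cutoff}")
    frame = profile.to_frame()
    called = frame[frame["Q"] > cutoff].copy()
    return called.sort_values("reference_position").reset_index(drop=True)


def conservation_summary(
    aln: Alignment, clusters: ClusterPair, columns: np.ndarray
) -> pd.DataFrame:
    """Per-site, per-cluster modal residue, modal fraction and composition.

    ``columns`` are 0-based alignment column indices. Gaps and unknowns are
    excluded from the denominators.
    """
    rows = []
    for name, members in (
        (clusters.name1, clusters.members1),
        (clusters.name2, clusters.members2),
    ):
        idx = aln.row_indices(sorted(members))
        for col in np.atleast_1d(columns):
            residues = aln.matrix[idx, col]
            residues = residues[(residues != GAP) & (residues != UNKNOWN)]
            if residues.size == 0:
                rows.append((int(col) + 1, name, "-", 0.0, ""))
                continue
            letters, counts = np.unique(residues, return_counts=True)
            order = np.lexsort((letters, -counts))
            modal = letters[order[0]]
            frac = counts[order[0]] / residues.size
            comp = ",".join(
                f"{letters[i]}:{counts[i]}" for i in order
            )
            rows.append((int(col) + 1, name, str(modal), float(frac), comp))
    return pd.DataFrame(
        rows, columns=["column_1based", "cluster", "modal", "modal_fraction", "composition"]
    )


def type2_pattern_check(
    column: int,
    aln: Alignment,
    clusters: ClusterPair,
    scheme: AAGroupScheme = DEFAULT_SCHEME,
    tau: float = 0.8,
) -> tuple[bool, dict]:
    """Verify the canonical type-II pattern at one alignment column (0-based).

    True iff both clusters are conserved (modal fraction >= tau) and the modal
    residues differ radically in physicochemical group.
    """
    summary = conservation_summary(aln, clusters, np.array([column]))
    row1 = summary[summary["cluster"] == clusters.name1].iloc[0]
    row2 = summary[summary["cluster"] == clusters.name2].iloc[0]
    conserved = row1["modal_fraction"] >= tau and row2["modal_fraction"] >= tau
    change = (
        classify_change(row1["modal"], row2["modal"], scheme)
        if row1["modal"] != "-" and row2["modal"] != "-"
        else "identical"
    )
    verdict = bool(conserved and change == "radical")
    report = {
        "column_1based": column + 1,
        "modal1": row1["modal"],
        "modal2": row2["modal"],
        "fraction1": float(row1["modal_fraction"]),
        "fraction2": float(row2["modal_fraction"]),
        "change_class": change,
        "conserved_both": bool(conserved),
        "pattern": verdict,
    }
    return verdict, report


def chi2_2x2(a: int, b: int, c: int, d: int) -> tuple[float, float]:
    """Pearson chi-square (1 df, no continuity correction) on a 2x2 table."""
    n = a + b + c + d
    num = n * (a * d - b * c) ** 2
    den = (a + b) * (c + d) * (a + c) * (b + d)
    if den == 0:
        return 0.0, 1.0
    stat = num / den
    return float(stat), float(chi2.sf(stat, df=1))


def enrichment_from_counts(
    n_overlap: int, n_divergent: int, n_binding: int, total_length: int,
    method: str = "chi-square",
) -> EnrichmentResult:
    """Enrichment test from the four marginal counts directly."""
    a = n_overlap
    b = n_divergent - n_overlap
    c = n_binding - n_overlap
    d = total_length - n_divergent - n_binding + n_overlap
    if min(a, b, c, d) < 0:
        raise ValueError("inconsistent counts for the 2x2 table")
    stat, p_chi2 = chi2_2x2(a, b, c, d)
    odds, p_fisher = fisher_exact([[a, b], [c, d]])
    n = a + b + c + d
    expected = [
        (a + b) * (a + c) / n, (a + b) * (b + d) / n,
        (c + d) * (a + c) / n, (c + d) * (b + d) / n,
    ]
    return EnrichmentResult(
        table=(a, b, c, d),
        chi2_stat=stat,
        p_chi2=p_chi2,
        p_fisher=float(p_fisher),
        odds_ratio=float(odds),
        method=method,
        small_expected=bool(min(expected) < 5),
    )


def enrichment_test(
    divergent: set[int] | list[int],
    binding: BindingSiteList | set[int] | list[int],
    total_length: int,
    method: str = "chi-square",
) -> EnrichmentResult:
    """Test enrichment of divergent residues within a binding-site list.

    Both site sets are 1-based reference positions; ``total_length`` is the
    number of residues scanned (defaults upstream to the reference's ungapped
    length). Pearson chi-square without continuity correction is the default;
    a Fisher exact p-value is always reported alongside, and the result is
    flagged when any expected cell is below 5.
    """
    if method not in ("chi-square", "fisher"):
        raise ValueError(f"unknown method {method!r}")
    div = set(int(p) for p in divergent)
    bind = set(
        binding.positions if isinstance(binding, BindingSiteList) else binding
    )
    bind = set(int(p) for p in bind)
    if total_length < len(div | bind):
        raise ValueError("total_length smaller than the union of site sets")
    if any(p > total_length for p in div | bind):
        raise ValueError("site position beyond total_length")
    return enrichment_from_counts(
        len(div & bind), len(div), len(bind), total_length, method=method
    )
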