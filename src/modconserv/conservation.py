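"""Per-column conservation scores for multi-strain alignments.

Five algorithms, each normalized to [0, 1] with 1 perfectly conserved and 0
random:

* ``shannon`` — 1 − H(p)/log 20 over the 20 standard amino acids;
* ``stereo`` — Shannon entropy over nine stereochemical groups, normalized
  by log 9, so physicochemically equivalent substitutions cost nothing;
* ``jsd`` — Jensen–Shannon divergence (λ = ½) between the column
  distribution and the BLOSUM62 background, normalized by its log 2 maximum;
* ``phylozoom`` — phylogeny-aware mismatch score anchored at a reference
  strain: a mismatch in a strain close to the reference is penalized
  heavily, one in a distant strain lightly.  The exact published weighting
  is not reproduced here; this is a property-equivalent stand-in using
  inverse patristic-distance weights (see the methods note);
* ``karlin`` — mean normalized substitution-matrix score over all residue
  pairs in the column, reranged from (−1, 1) to (0, 1).

Gaps are the symbols {X, B, Z, '-'}.  Entropy-family scores drop gaps
before computing frequencies; the optional multiplicative gap penalty
(score × non-gap fraction) applies to every algorithm except ``karlin``,
whose pairwise sum already loses evidence when gapped rows are excluded.

Columns with no usable symbols yield ``nan`` (not 0, which would read as
"random"); downstream window averages skip ``nan``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from ._tables import (
    AA_INDEX,
    AMINO_ACIDS,
    BLOSUM62_BACKGROUND,
    GAP_SYMBOLS,
    STEREO_GROUP_OF,
    substitution_lookup,
)
from .alignments import StrainAlignment, StrainTree

ALGORITHMS = ("shannon", "stereo", "jsd", "phylozoom", "karlin")

_LOG20 = math.log(20.0)
_LOG9 = math.log(9.0)
_LOG2 = math.log(2.0)


def _residues(column: Iterable[str]) -> list[str]:
    return [s for s in column if s not in GAP_SYMBOLS]


def _entropy(freqs: np.ndarray) -> float:
    nz = freqs[freqs > 0]
    return float(-(nz * np.log(nz)).sum())


def _aa_distribution(residues: Sequence[str]) -> np.ndarray:
    counts = np.zeros(20)
    for r in residues:
        counts[AA_INDEX[r]] += 1
    return counts / counts.sum()


def shannon_score(column: Iterable[str]) -> float:
    """1 − normalized Shannon entropy of the non-gap residues."""
    residues = _residues(column)
    if not residues:
        return float("nan")
    return 1.0 - _entropy(_aa_distribution(residues)) / _LOG20


def stereo_entropy_score(column: Iterable[str]) -> float:
    """Shannon score over the nine stereochemical groups (log 9 normalized)."""
    residues = _residues(column)
    if not residues:
        return float("nan")
    counts = np.zeros(len(set(STEREO_GROUP_OF.values())))
    for r in residues:
        counts[STEREO_GROUP_OF[r]] += 1
    return 1.0 - _entropy(counts / counts.sum()) / _LOG9


def jsd_score(column: Iterable[str],
              background: np.ndarray | None = None) -> float:
    """Jensen–Shannon divergence from the background, scaled to [0, 1].

    0 means the column looks exactly like the no-selection background;
    1 is maximal divergence (log 2 with λ = ½).
    """
    residues = _residues(column)
    if not residues:
        return float("nan")
    q = BLOSUM62_BACKGROUND if background is None else np.asarray(background, float)
    p = _aa_distribution(residues)
    m = 0.5 * (p + q)
    jsd = _entropy(m) - 0.5 * (_entropy(p) + _entropy(q))
    return min(1.0, max(0.0, jsd / _LOG2))


def phylozoom_score(
    column_by_strain: Mapping[str, str],
    tree: StrainTree,
    reference: str,
    epsilon: float | None = None,
) -> float:
    """Inverse-distance-weighted mismatch score anchored at the reference.

    score = 1 − Σ wᵢ·1[aᵢ ≠ a_ref] / Σ wᵢ over non-gap comparison strains,
    wᵢ = 1/(dᵢ + ε) with dᵢ the patristic distance to the reference and
    ε a small positive constant (default 1e-6 × tree diameter).  Stand-in
    for the published phylogeny-weighted entropy; satisfies its stated
    properties (1 when monomorphic; mismatches near the reference penalized
    more than distant ones; reduces to the match fraction on a star tree).
    """
    if reference not in column_by_strain:
        raise KeyError(f"reference strain {reference!r} missing from column")
    ref_sym = column_by_strain[reference]
    if ref_sym in GAP_SYMBOLS:
        return float("nan")
    if epsilon is None:
        diam = tree.diameter()
        epsilon = 1e-6 * diam if diam > 0 else 1e-6
    num = den = 0.0
    for strain, sym in column_by_strain.items():
        if strain == reference or sym in GAP_SYMBOLS:
            continue
        w = 1.0 / (tree.distance(strain, reference) + epsilon)
        den += w
        if sym != ref_sym:
            num += w
    if den == 0.0:
        return float("nan")
    return 1.0 - num / den


def karlin_score(column: Iterable[str],
                 substitution: Mapping[tuple[str, str], float] | None = None) -> float:
    """Mean normalized pairwise substitution score, reranged to [0, 1].

    s = (2/(n(n−1))) Σ_{i<j} M(aᵢ,aⱼ)/√(M(aᵢ,aᵢ)·M(aⱼ,aⱼ)) over non-gap
    residues, then (s+1)/2.  Gapped rows are simply excluded from the sum.
    """
    residues = _residues(column)
    if len(residues) < 2:
        return float("nan")
    sub = substitution if substitution is not None else substitution_lookup("BLOSUM62")
    counts: dict[str, int] = {}
    for r in residues:
        counts[r] = counts.get(r, 0) + 1
    symbols = sorted(counts)
    n = len(residues)
    total = 0.0
    for i, a in enumerate(symbols):
        ca = counts[a]
        total += 1.0 * (ca * (ca - 1) / 2)  # M(a,a)/sqrt(M(a,a)^2) = 1
        for b in symbols[i + 1:]:
            norm = math.sqrt(sub[(a, a)] * sub[(b, b)])
            total += ca * counts[b] * sub[(a, b)] / norm
    s = 2.0 * total / (n * (n - 1))
    return (s + 1.0) / 2.0


def gap_fraction(column: Iterable[str]) -> float:
    syms = list(column)
    return sum(1 for s in syms if s in GAP_SYMBOLS) / len(syms)


def apply_gap_penalty(score: float, column: Iterable[str]) -> float:
    """Multiply a score by the column's non-gap fraction."""
    if math.isnan(score):
        return score
    return score * (1.0 - gap_fraction(column))


@dataclass
class ScoringConfig:
    """Which algorithm to run and everything it needs."""

    algorithm: str = "shannon"
    gap_penalty: bool = False
    reference_strain: str | None = None
    background: np.ndarray | None = None
    substitution: Mapping[tuple[str, str], float] | None = None
    tree: StrainTree | None = None
    epsilon: float | None = None

    def __post_init__(self) -> None:
        if self.algorithm not in ALGORITHMS:
            raise ValueError(f"unknown algorithm {self.algorithm!r}")
        if self.background is not None:
            total = float(np.sum(self.background))
            if abs(total - 1.0) > 1e-9:
                raise ValueError("background frequencies must sum to 1")
        if self.algorithm == "phylozoom" and self.tree is None:
            raise ValueError("phylozoom requires a strain tree")


@dataclass
class ConservationProfile:
    """Per-column scores for one ORF under one algorithm/configuration."""

    orf_id: str
    algorithm: str
    scores: np.ndarray                    # length L, nan where undefined
    gap_fractions: np.ndarray             # length L
    ref_positions: np.ndarray             # length L; 0 where reference gapped
    reference_sequence: str
    by_position: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        npos = len(self.reference_sequence)
        by_pos = np.full(npos, np.nan)
        for col, pos in enumerate(self.ref_positions):
            if pos > 0:
                by_pos[pos - 1] = self.scores[col]
        self.by_position = by_pos

    def score_at_position(self, position: int) -> float:
        """Score at a 1-based ungapped reference position."""
        if not 1 <= position <= len(self.by_position):
            raise IndexError(f"position {position} out of range")
        return float(self.by_position[position - 1])


def score_column(aln: StrainAlignment, column: int, config: ScoringConfig) -> float:
    col = aln.column(column)
    if config.algorithm == "shannon":
        score = shannon_score(col)
    elif config.algorithm == "stereo":
        score = stereo_entropy_score(col)
    elif config.algorithm == "jsd":
        score = jsd_score(col, config.background)
    elif config.algorithm == "phylozoom":
        ref = config.reference_strain or aln.reference_strain
        score = phylozoom_score(aln.column_by_strain(column), config.tree,
                                ref, config.epsilon)
    else:
        score = karlin_score(col, config.substitution)
    if config.gap_penalty and config.algorithm != "karlin":
        score = apply_gap_penalty(score, col)
    return score


def score_profile(aln: StrainAlignment, config: ScoringConfig) -> ConservationProfile:
    """Score every column of an alignment under one configuration."""
    L = aln.length
    scores = np.array([score_column(aln, c, config) for c in range(1, L + 1)])
    gaps = np.array([gap_fraction(aln.column(c)) for c in range(1, L + 1)])
    ref_row = aln.reference_row
    ref_positions = np.zeros(L, dtype=int)
    pos = 0
    for i, sym in enumerate(ref_row):
        if sym not in GAP_SYMBOLS:
            pos += 1
            ref_positions[i] = pos
    return ConservationProfile(
        orf_id=aln.orf_id,
        algorithm=config.algorithm,
        scores=scores,
        gap_fractions=gaps,
        ref_positions=ref_positions,
        reference_sequence=aln.reference_sequence,
    )
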