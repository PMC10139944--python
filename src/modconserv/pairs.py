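"""Global alignment of paralog pairs and enumeration of differentially
modified sites.

The two reference protein sequences of a paralog pair are aligned with the
Needleman–Wunsch algorithm under an affine gap cost in which a gap of length
k costs ``gap_open + k * gap_extend`` (so a single-residue gap costs 10.5
with the default parameters).  End gaps are penalized like internal gaps.
Among co-optimal alignments the traceback prefers diagonal over up over
left, which makes the reported alignment deterministic.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

from ._tables import AMINO_ACIDS, substitution_lookup
from .alignments import ModificationRecord, ParalogPair, StrainAlignment

DEFAULT_GAP_OPEN = 10.0
DEFAULT_GAP_EXTEND = 0.5

_NEG_INF = float("-inf")


class MissingSequenceError(KeyError):
    """An ORF referenced by a pair has no reference sequence."""


class MotifQueryError(ValueError):
    """A motif query contains characters outside the residue alphabet + 'X'."""


@dataclass(frozen=True)
class SiteMap:
    """Column-level correspondence between the two members of a pair."""

    pair: ParalogPair
    aligned_a: str
    aligned_b: str
    score: float

    def __post_init__(self) -> None:
        if len(self.aligned_a) != len(self.aligned_b):
            raise ValueError("aligned strings differ in length")

    @property
    def correspondence(self) -> list[tuple[int | None, int | None]]:
        """Per column: (1-based ungapped position in a | None, same for b)."""
        out: list[tuple[int | None, int | None]] = []
        ia = ib = 0
        for ca, cb in zip(self.aligned_a, self.aligned_b):
            pa = pb = None
            if ca != "-":
                ia += 1
                pa = ia
            if cb != "-":
                ib += 1
                pb = ib
            out.append((pa, pb))
        return out

    def position_map_a_to_b(self) -> dict[int, int]:
        """Map of mutually aligned (non-gap ↔ non-gap) positions, a → b."""
        return {
            pa: pb for pa, pb in self.correspondence
            if pa is not None and pb is not None
        }


def needleman_wunsch_align(
    seq_a: str,
    seq_b: str,
    substitution: Mapping[tuple[str, str], float] | None = None,
    gap_open: float = DEFAULT_GAP_OPEN,
    gap_extend: float = DEFAULT_GAP_EXTEND,
    pair: ParalogPair | None = None,
) -> SiteMap:
    """Optimal global alignment under affine gap cost (Gotoh recursion).

    A gap of length k subtracts ``gap_open + k * gap_extend`` from the summed
    substitution scores.  ``substitution`` defaults to BLOSUM62.
    """
    if not seq_a or not seq_b:
        raise ValueError("cannot align an empty sequence")
    sub = substitution if substitution is not None else substitution_lookup("BLOSUM62")
    n, m = len(seq_a), len(seq_b)

    # M: a_i aligned to b_j;  X: gap in b (consume a, move up);  Y: gap in a.
    M = np.full((n + 1, m + 1), _NEG_INF)
    X = np.full((n + 1, m + 1), _NEG_INF)
    Y = np.full((n + 1, m + 1), _NEG_INF)
    M[0, 0] = 0.0
    for i in range(1, n + 1):
        X[i, 0] = -(gap_open + i * gap_extend)
    for j in range(1, m + 1):
        Y[0, j] = -(gap_open + j * gap_extend)

    open_cost = gap_open + gap_extend  # first gapped residue

    for i in range(1, n + 1):
        ai = seq_a[i - 1]
        for j in range(1, m + 1):
            s = sub[(ai, seq_b[j - 1])]
            best_prev = max(M[i - 1, j - 1], X[i - 1, j - 1], Y[i - 1, j - 1])
            M[i, j] = best_prev + s
            X[i, j] = max(
                M[i - 1, j] - open_cost,
                X[i - 1, j] - gap_extend,
                Y[i - 1, j] - open_cost,
            )
            Y[i, j] = max(
                M[i, j - 1] - open_cost,
                Y[i, j - 1] - gap_extend,
                X[i, j - 1] - open_cost,
            )

    score = max(M[n, m], X[n, m], Y[n, m])

    # Traceback; preference diagonal (M) > up (X) > left (Y) on ties.
    out_a: list[str] = []
    out_b: list[str] = []
    i, j = n, m
    state = max(("M", "X", "Y"), key=lambda st: ({"M": M, "X": X, "Y": Y}[st][n, m],
                                                 {"M": 2, "X": 1, "Y": 0}[st]))
    while i > 0 or j > 0:
        if state == "M":
            out_a.append(seq_a[i - 1])
            out_b.append(seq_b[j - 1])
            s = sub[(seq_a[i - 1], seq_b[j - 1])]
            target = M[i, j] - s
            i, j = i - 1, j - 1
            for st, mat in (("M", M), ("X", X), ("Y", Y)):
                if np.isclose(mat[i, j], target):
                    state = st
                    break
        elif state == "X":
            out_a.append(seq_a[i - 1])
            out_b.append("-")
            here = X[i, j]
            i -= 1
            if np.isclose(M[i, j] - open_cost, here):
                state = "M"
            elif np.isclose(X[i, j] - gap_extend, here):
                state = "X"
            else:
                state = "Y"
        else:
            out_a.append("-")
            out_b.append(seq_b[j - 1])
            here = Y[i, j]
            j -= 1
            if np.isclose(M[i, j] - open_cost, here):
                state = "M"
            elif np.isclose(Y[i, j] - gap_extend, here):
                state = "Y"
            else:
                state = "X"
        if i == 0 and j == 0:
            break
        if i == 0 and state != "Y":
            state = "Y"
        if j == 0 and state != "X":
            state = "X"

    return SiteMap(
        pair=pair if pair is not None else ParalogPair("a", "b"),
        aligned_a="".join(reversed(out_a)),
        aligned_b="".join(reversed(out_b)),
        score=float(score),
    )


@dataclass(frozen=True)
class SiteOfInterest:
    """An aligned residue identical in both paralogs, modified in one only."""

    pair: ParalogPair
    target_orf: str
    mod_type: str
    residue: str
    target_position: int
    paralog_position: int

    @property
    def paralog_orf(self) -> str:
        return self.pair.orf_b if self.target_orf == self.pair.orf_a else self.pair.orf_a


def find_sites_of_interest(
    pairs: Iterable[ParalogPair],
    mods: Iterable[ModificationRecord],
    sequences: Mapping[str, str],
    gap_open: float = DEFAULT_GAP_OPEN,
    gap_extend: float = DEFAULT_GAP_EXTEND,
) -> list[SiteOfInterest]:
    """Enumerate, per modification type, positions identical in both paralogs
    where exactly one member is modified.

    Residue substitutions are never accepted (an S↔T alignment is excluded
    even though both are phosphorylatable); positions modified in both
    members are excluded because neither provides an unmodified partner.
    """
    mods_by_orf: dict[tuple[str, str], dict[int, ModificationRecord]] = {}
    for m in mods:
        mods_by_orf.setdefault((m.orf_id, m.mod_type), {})[m.position] = m

    out: list[SiteOfInterest] = []
    for pair in pairs:
        for orf in (pair.orf_a, pair.orf_b):
            if orf not in sequences:
                raise MissingSequenceError(f"no sequence for {orf}")
        seq_a, seq_b = sequences[pair.orf_a], sequences[pair.orf_b]
        sm = needleman_wunsch_align(seq_a, seq_b, gap_open=gap_open,
                                    gap_extend=gap_extend, pair=pair)
        pos_map = sm.position_map_a_to_b()
        mod_types = {mt for (orf, mt) in mods_by_orf if orf in (pair.orf_a, pair.orf_b)}
        for mt in sorted(mod_types):
            mods_a = mods_by_orf.get((pair.orf_a, mt), {})
            mods_b = mods_by_orf.get((pair.orf_b, mt), {})
            for pa, pb in sorted(pos_map.items()):
                ra, rb = seq_a[pa - 1], seq_b[pb - 1]
                if ra != rb:
                    continue
                a_mod, b_mod = pa in mods_a, pb in mods_b
                if a_mod == b_mod:
                    continue
                target = pair.orf_a if a_mod else pair.orf_b
                tp, pp = (pa, pb) if a_mod else (pb, pa)
                out.append(
                    SiteOfInterest(
                        pair=pair, target_orf=target, mod_type=mt, residue=ra,
                        target_position=tp, paralog_position=pp,
                    )
                )
    return out


def motif_search(aln: StrainAlignment, query: str | Sequence[int]) -> list[int]:
    """Match a motif (or validate a position list) against the ungapped
    reference sequence; 'X' in a motif matches any residue.

    Returns 1-based start positions of every (possibly overlapping) match.
    """
    ref = aln.reference_sequence
    if not isinstance(query, str):
        for pos in query:
            if not 1 <= int(pos) <= len(ref):
                raise IndexError(f"position {pos} outside 1..{len(ref)}")
        return [int(p) for p in query]
    if not query:
        raise MotifQueryError("empty motif")
    bad = set(query.upper()) - set(AMINO_ACIDS) - {"X"}
    if bad:
        raise MotifQueryError(f"illegal motif characters {sorted(bad)}")
    pattern = query.upper().replace("X", ".")
    return [m.start() + 1 for m in re.finditer(f"(?={pattern})", ref)]
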