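"""Kinase-interaction summaries, PWM kinase assignment, abundance and
multi-study filters, and secondary-structure comparisons from STRIDE output.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from ._tables import AMINO_ACIDS
from .alignments import AbundanceRecord, ModificationRecord, ParalogPair
from .pairs import SiteOfInterest

logger = logging.getLogger(__name__)

#: STRIDE one-letter → descriptive secondary-structure class.
STRIDE_CLASSES = {
    "H": "AlphaHelix", "G": "310Helix", "I": "PiHelix",
    "E": "Strand", "B": "Bridge", "b": "Bridge",
    "T": "Turn", "C": "Coil",
}


@dataclass(frozen=True)
class KinaseInteraction:
    kinase_id: str
    substrate_orf: str
    evidence: str = ""


class KinaseInteractionTable:
    """Deduplicated (kinase, substrate) interaction table."""

    def __init__(self, interactions: Iterable[KinaseInteraction]):
        seen: dict[tuple[str, str], KinaseInteraction] = {}
        for it in interactions:
            seen.setdefault((it.kinase_id, it.substrate_orf), it)
        self._rows = list(seen.values())
        self._by_substrate: dict[str, set[str]] = {}
        for it in self._rows:
            self._by_substrate.setdefault(it.substrate_orf, set()).add(it.kinase_id)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "KinaseInteractionTable":
        df = pd.read_csv(path, sep="\t", dtype=str)
        cols = list(df.columns)
        rows = [
            KinaseInteraction(str(r[cols[0]]), str(r[cols[1]]),
                              str(r[cols[2]]) if len(cols) > 2 else "")
            for _, r in df.iterrows()
        ]
        return cls(rows)

    def __len__(self) -> int:
        return len(self._rows)

    def kinases_of(self, orf: str) -> set[str]:
        return set(self._by_substrate.get(orf, set()))


def single_interaction_ratio(pair: ParalogPair,
                             table: KinaseInteractionTable) -> float | None:
    """#kinases touching exactly one member / #kinases touching ≥ one member.

    Returns None when no kinase interacts with either member.
    """
    ka = table.kinases_of(pair.orf_a)
    kb = table.kinases_of(pair.orf_b)
    single = len(ka ^ kb)
    double = len(ka & kb)
    if single + double == 0:
        return None
    return single / (single + double)


@dataclass
class PWM:
    """Position-weight matrix over offsets relative to the phosphosite."""

    kinase_id: str
    offsets: tuple[int, ...]                 # e.g. -5..+4, excluding 0 or not
    weights: np.ndarray                      # len(offsets) × 20, AMINO_ACIDS order

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        if self.weights.shape != (len(self.offsets), 20):
            raise ValueError("weights must be n_offsets × 20")


def read_pwms(path: str | Path) -> list[PWM]:
    """Read PWMs from a TSV with columns kinase, position, then 20 residues."""
    df = pd.read_csv(path, sep="\t")
    aa_cols = [c for c in df.columns if c in set(AMINO_ACIDS)]
    if len(aa_cols) != 20:
        raise ValueError("PWM table needs one column per standard amino acid")
    pwms = []
    for kinase, grp in df.groupby(df.columns[0], sort=True):
        grp = grp.sort_values(df.columns[1])
        offsets = tuple(int(x) for x in grp[df.columns[1]])
        weights = grp[list(AMINO_ACIDS)].to_numpy(dtype=float)
        pwms.append(PWM(str(kinase), offsets, weights))
    return pwms


def pwm_site_score(pwm: PWM, sequence: str, position: int) -> float:
    """Summed PWM weight over the window around a 1-based site position.

    Offsets falling outside the sequence are skipped (no padding) and their
    weights omitted from the sum.
    """
    aa_index = {aa: i for i, aa in enumerate(AMINO_ACIDS)}
    total = 0.0
    for row, off in enumerate(pwm.offsets):
        pos = position + off
        if not 1 <= pos <= len(sequence):
            continue
        aa = sequence[pos - 1]
        if aa in aa_index:
            total += pwm.weights[row, aa_index[aa]]
    return total


def assign_best_kinase(site: SiteOfInterest | int, sequence: str,
                       pwms: Sequence[PWM]) -> str:
    """Kinase whose PWM maximizes the summed weight at the site.

    Ties break deterministically toward the lexicographically first kinase
    identifier.
    """
    if not pwms:
        raise ValueError("empty PWM list")
    position = site if isinstance(site, int) else site.target_position
    best = max(
        sorted(pwms, key=lambda p: p.kinase_id),
        key=lambda p: pwm_site_score(p, sequence, position),
    )
    # max() keeps the first of equal keys, i.e. the lexicographically first.
    return best.kinase_id


def disjoint_kinase_pairs(
    phosphosites_by_pair: Mapping[ParalogPair, tuple[Sequence[int], Sequence[int]]],
    sequences: Mapping[str, str],
    pwms: Sequence[PWM],
) -> list[ParalogPair]:
    """Pairs whose assigned-kinase sets (one per member) are disjoint.

    Only pairs in which both members carry at least one qualifying
    phosphosite belong in the input mapping.
    """
    out = []
    for pair, (sites_a, sites_b) in phosphosites_by_pair.items():
        if not sites_a or not sites_b:
            continue
        ka = {assign_best_kinase(p, sequences[pair.orf_a], pwms) for p in sites_a}
        kb = {assign_best_kinase(p, sequences[pair.orf_b], pwms) for p in sites_b}
        if not ka & kb:
            out.append(pair)
    return out


def filter_pairs_by_abundance(
    pairs: Iterable[ParalogPair],
    abundances: Mapping[str, AbundanceRecord],
    max_fold: float = 2.0,
) -> list[ParalogPair]:
    """Keep pairs whose members' median abundances differ by < max_fold."""
    if not max_fold > 1:
        raise ValueError("max_fold must exceed 1")
    kept, dropped_missing = [], 0
    for pair in pairs:
        ra = abundances.get(pair.orf_a)
        rb = abundances.get(pair.orf_b)
        if ra is None or rb is None:
            dropped_missing += 1
            continue
        a, b = ra.median_abundance, rb.median_abundance
        if max(a, b) / min(a, b) < max_fold:
            kept.append(pair)
    if dropped_missing:
        logger.info("dropped %d pairs lacking abundance data", dropped_missing)
    return kept


def filter_multi_study(mods: Iterable[ModificationRecord],
                       min_studies: int = 2) -> list[ModificationRecord]:
    """Keep modifications reported by at least ``min_studies`` studies."""
    if min_studies < 1:
        raise ValueError("min_studies must be >= 1")
    return [m for m in mods if len(m.study_ids) >= min_studies]


@dataclass(frozen=True)
class StrideRecord:
    orf_id: str
    position: int
    residue: str
    secondary_structure: str
    solvent_accessible_area: float

    def __post_init__(self) -> None:
        if self.solvent_accessible_area < 0:
            raise ValueError("solvent accessible area must be >= 0")


class StrideParseError(ValueError):
    pass


def parse_stride(path: str | Path, orf_id: str | None = None) -> list[StrideRecord]:
    """Parse ASG lines of a STRIDE detailed secondary-structure assignment.

    ASG columns: residue name, chain, PDB number, ordinal number, one-letter
    structure code, structure name, phi, psi, solvent accessible area.
    Non-contiguous residue numbering only warns.
    """
    path = Path(path)
    records: list[StrideRecord] = []
    three_to_one = {
        "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
        "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
        "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
        "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
    }
    name = orf_id or path.stem
    last_pos: int | None = None
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        if not line.startswith("ASG"):
            continue
        fields = line.split()
        if len(fields) < 10:
            raise StrideParseError(f"malformed ASG line {lineno}: {line!r}")
        try:
            position = int(fields[3])
            code = fields[5]
            area = float(fields[9])
        except ValueError as exc:
            raise StrideParseError(f"malformed ASG line {lineno}: {exc}") from exc
        structure = STRIDE_CLASSES.get(code)
        if structure is None:
            raise StrideParseError(f"unknown structure code {code!r} at line {lineno}")
        if last_pos is not None and position != last_pos + 1:
            logger.warning("non-contiguous residue numbering at line %d", lineno)
        last_pos = position
        records.append(StrideRecord(
            orf_id=name,
            position=position,
            residue=three_to_one.get(fields[1], "X"),
            secondary_structure=structure,
            solvent_accessible_area=area,
        ))
    return records


def secondary_structure_length(records: Sequence[StrideRecord],
                               position: int) -> int | None:
    """Length of the uninterrupted same-class run containing a position."""
    by_pos = {r.position: r for r in records}
    rec = by_pos.get(position)
    if rec is None:
        return None
    cls = rec.secondary_structure
    length = 1
    p = position - 1
    while p in by_pos and by_pos[p].secondary_structure == cls:
        length += 1
        p -= 1
    p = position + 1
    while p in by_pos and by_pos[p].secondary_structure == cls:
        length += 1
        p += 1
    return length


def pair_structure_difference(
    site: SiteOfInterest,
    target_records: Sequence[StrideRecord],
    paralog_records: Sequence[StrideRecord],
) -> tuple[str, int, float] | None:
    """(class-pair label, Δrun-length, Δaccessible-area), target minus paralog.

    The class-pair label is ordered target-first (Coil-Turn ≠ Turn-Coil).
    Returns None when either position lacks structure coverage.
    """
    t_by_pos = {r.position: r for r in target_records}
    p_by_pos = {r.position: r for r in paralog_records}
    t = t_by_pos.get(site.target_position)
    p = p_by_pos.get(site.paralog_position)
    if t is None or p is None:
        return None
    t_len = secondary_structure_length(target_records, site.target_position)
    p_len = secondary_structure_length(paralog_records, site.paralog_position)
    label = f"{t.secondary_structure}-{p.secondary_structure}"
    return (label, t_len - p_len,
            t.solvent_accessible_area - p.solvent_accessible_area)
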