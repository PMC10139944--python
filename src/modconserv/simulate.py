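"""Seed-deterministic synthetic data with controlled statistical structure.

The generator emulates the shape of the real inputs — per-ORF multi-strain
alignments, a paralog-pair table, a modification-site table, a strain
phylogeny — while giving the tests knobs the real data lack:

* per-column conservation is specified directly, so score recovery can be
  checked against a known target;
* each paralog pair shares a per-position base conservation (paralogs share
  an evolutionary history); a ``flank_advantage`` δ adds conservation in the
  ±4-residue windows around "modified" sites of targets only.  δ = 0 makes
  target and paralog window scores exchangeable (the null);
* the motif generator plants a residue enrichment at one relative position
  of the target flank.

Everything is driven by ``numpy.random.default_rng(seed)``; identical
configurations regenerate identical data.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np

from ._tables import AMINO_ACIDS, BLOSUM62_BACKGROUND
from .alignments import ModificationRecord, ParalogPair, StrainAlignment, StrainTree
from .pairs import SiteOfInterest
from .windows import PairedScoreSet, ScorePair


@dataclass
class SimulationConfig:
    n_strains: int = 16
    n_pairs: int = 60
    sites_per_pair: int = 2
    protein_length: int = 30
    conservation_base: float = 0.6
    flank_advantage: float = 0.0           # δ, added in ±4 windows of targets
    flank_halfwidth: int = 4
    motif_plant: tuple[str, str, float] | None = None  # (rel. position, residue, factor)
    seed: int = 0
    background: np.ndarray = field(default_factory=lambda: BLOSUM62_BACKGROUND)

    def __post_init__(self) -> None:
        if not 0.0 <= self.conservation_base <= 1.0:
            raise ValueError("conservation_base must lie in [0, 1]")
        if self.flank_advantage < 0:
            raise ValueError("flank_advantage must be >= 0")


def _draw_residues(rng: np.random.Generator, n: int,
                   background: np.ndarray) -> np.ndarray:
    return rng.choice(list(AMINO_ACIDS), size=n, p=background)


def simulate_alignment(
    orf_id: str,
    length: int,
    per_column_conservation: Sequence[float],
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
    consensus: str | None = None,
    reference_strain: str = "S288C",
) -> StrainAlignment:
    """Alignment whose columns keep a consensus residue with the requested
    probability and otherwise draw from the background distribution.

    The reference strain always carries the consensus, so the ungapped
    reference sequence equals the consensus sequence.
    """
    cons = np.asarray(per_column_conservation, dtype=float)
    if cons.shape != (length,):
        raise ValueError("conservation vector length must equal alignment length")
    if np.any((cons < 0) | (cons > 1)):
        raise ValueError("conservation values must lie in [0, 1]")
    if rng is None:
        rng = np.random.default_rng(config.seed)
    if consensus is None:
        consensus = "".join(_draw_residues(rng, length, config.background))
    elif len(consensus) != length:
        raise ValueError("consensus length must equal alignment length")

    n_other = config.n_strains - 1
    keep = rng.random((n_other, length)) < cons[None, :]
    noise = _draw_residues(rng, n_other * length, config.background
                           ).reshape(n_other, length)
    cons_arr = np.array(list(consensus))
    mat = np.where(keep, cons_arr[None, :], noise)
    strain_ids = (reference_strain,) + tuple(f"strain{i:04d}" for i in range(n_other))
    rows = (consensus,) + tuple("".join(r) for r in mat)
    return StrainAlignment(orf_id=orf_id, strain_ids=strain_ids, rows=rows,
                           reference_strain=reference_strain)


def simulate_strain_tree(n_strains: int, seed: int = 0,
                         reference_strain: str = "S288C") -> StrainTree:
    """Random binary tree with exponential branch lengths over the strains."""
    rng = np.random.default_rng(seed)
    labels = [reference_strain] + [f"strain{i:04d}" for i in range(n_strains - 1)]
    nodes = [lab for lab in labels]
    while len(nodes) > 1:
        i, j = rng.choice(len(nodes), size=2, replace=False)
        a, b = nodes[int(i)], nodes[int(j)]
        la, lb = rng.exponential(0.1, size=2)
        merged = f"({a}:{la:.6f},{b}:{lb:.6f})"
        nodes = [n for k, n in enumerate(nodes) if k not in (int(i), int(j))]
        nodes.append(merged)
    return StrainTree.from_newick(nodes[0] + ";")


def _site_positions(config: SimulationConfig) -> list[int]:
    """Interior site positions with full ±4 flanks, evenly spaced."""
    margin = config.flank_halfwidth + 1
    usable = config.protein_length - 2 * margin
    if usable < config.sites_per_pair:
        raise ValueError("protein too short for the requested sites")
    step = usable // config.sites_per_pair
    return [margin + 1 + i * step for i in range(config.sites_per_pair)]


def simulate_paralog_dataset(
    config: SimulationConfig,
) -> tuple[dict[str, StrainAlignment], list[ParalogPair], list[ModificationRecord]]:
    """Alignments, pairs and modification records for a paralog experiment.

    Both members of a pair carry the *same* reference protein sequence with
    a serine at every planted site, so every planted site is a valid site of
    interest.  Per-position base conservation is shared within the pair;
    targets additionally receive ``flank_advantage`` around their modified
    sites.  With ``flank_advantage == 0`` the two members are exchangeable.
    """
    rng = np.random.default_rng(config.seed)
    L = config.protein_length
    site_positions = _site_positions(config)

    alignments: dict[str, StrainAlignment] = {}
    pairs: list[ParalogPair] = []
    mods: list[ModificationRecord] = []
    for i in range(config.n_pairs):
        orf_a, orf_b = f"ORFA{i:04d}", f"ORFB{i:04d}"
        pairs.append(ParalogPair(orf_a, orf_b))

        seq = list(_draw_residues(rng, L, config.background))
        for pos in site_positions:
            seq[pos - 1] = "S"
        consensus = "".join(seq)

        base = np.clip(
            config.conservation_base + rng.uniform(-0.25, 0.25, size=L),
            0.05, 0.95,
        )
        target_cons = base.copy()
        if config.flank_advantage > 0:
            for pos in site_positions:
                lo = max(0, pos - 1 - config.flank_halfwidth)
                hi = min(L, pos + config.flank_halfwidth)
                target_cons[lo:hi] = np.clip(
                    target_cons[lo:hi] + config.flank_advantage, 0.0, 0.995
                )
        alignments[orf_a] = simulate_alignment(
            orf_a, L, target_cons, config, rng=rng, consensus=consensus)
        alignments[orf_b] = simulate_alignment(
            orf_b, L, base, config, rng=rng, consensus=consensus)

        for pos in site_positions:
            mods.append(ModificationRecord(
                orf_id=orf_a, position=pos, residue="S",
                mod_type="phosphorylation", study_ids=frozenset({"s1", "s2"}),
            ))
    return alignments, pairs, mods


def simulate_motif_dataset(
    config: SimulationConfig,
) -> tuple[list[SiteOfInterest], dict[str, str]]:
    """Sites and sequences with an optional planted flanking-residue motif.

    Each "pair" contributes one phosphoserine site; flanking residues are
    background draws except that, at the planted relative position (e.g.
    ``b3``), the target's residue is drawn from the background tilted by the
    enrichment factor toward the planted residue.  Factor 1 (or no plant)
    makes target and paralog flanks exchangeable.
    """
    rng = np.random.default_rng(config.seed)
    L = config.protein_length
    site_pos = L // 2
    plant_offset = None
    tilted = None
    if config.motif_plant is not None:
        rel, residue, factor = config.motif_plant
        if factor < 1:
            raise ValueError("enrichment factor must be >= 1")
        k = int(rel[1])
        plant_offset = -k if rel[0] == "b" else k
        tilted = config.background.copy()
        tilted[AMINO_ACIDS.index(residue)] *= factor
        tilted = tilted / tilted.sum()

    sites: list[SiteOfInterest] = []
    sequences: dict[str, str] = {}
    for i in range(config.n_pairs):
        orf_t, orf_p = f"TGT{i:04d}", f"PAR{i:04d}"
        tseq = list(_draw_residues(rng, L, config.background))
        pseq = list(_draw_residues(rng, L, config.background))
        tseq[site_pos - 1] = pseq[site_pos - 1] = "S"
        if plant_offset is not None:
            tseq[site_pos - 1 + plant_offset] = str(
                rng.choice(list(AMINO_ACIDS), p=tilted))
        sequences[orf_t] = "".join(tseq)
        sequences[orf_p] = "".join(pseq)
        sites.append(SiteOfInterest(
            pair=ParalogPair(orf_t, orf_p), target_orf=orf_t,
            mod_type="phosphorylation", residue="S",
            target_position=site_pos, paralog_position=site_pos,
        ))
    return sites, sequences


def _score_set(target: np.ndarray, paralog: np.ndarray,
               statistic: str = "mean1") -> PairedScoreSet:
    pairs = []
    for i, (t, p) in enumerate(zip(target, paralog)):
        site = SiteOfInterest(
            pair=ParalogPair(f"TGT{i:04d}", f"PAR{i:04d}"),
            target_orf=f"TGT{i:04d}", mod_type="phosphorylation", residue="S",
            target_position=10, paralog_position=10,
        )
        pairs.append(ScorePair(site, float(t), float(p)))
    return PairedScoreSet("phosphorylation", "shannon", statistic, pairs)


def scenario_separated(n: int = 50, seed: int = 0) -> PairedScoreSet:
    """Non-overlapping distributions: every target beats every paralog.

    The distribution-mean test is unavoidably significant; the pairing test
    cannot be (every shuffle also scores 1, so the authentic pairing never
    beats a shuffle).
    """
    rng = np.random.default_rng(seed)
    return _score_set(rng.uniform(0.7, 0.9, n), rng.uniform(0.1, 0.3, n))


def scenario_paired_advantage(n: int = 50, seed: int = 0) -> PairedScoreSet:
    """Heavily overlapping marginals with a within-pair target advantage:
    both tests should reject."""
    rng = np.random.default_rng(seed)
    base = rng.uniform(0.2, 0.8, n)
    return _score_set(base + rng.uniform(0.01, 0.05, n), base)


def scenario_matched_marginals(n: int = 100, seed: int = 0) -> PairedScoreSet:
    """Matched, substantially overlapping marginals whose pairing still
    advantages the target: pairing test significant, mean test not.

    ~71% of pairs are narrow target wins and ~29% large target losses, so
    the win fraction is far above the shuffle null while the signed ranks
    balance (W⁺ ≈ n(n+1)/4) and the Wilcoxon test stays non-significant.
    """
    rng = np.random.default_rng(seed)
    n_win = round(0.71 * n)
    base_win = rng.uniform(0.30, 0.65, n_win)
    t_win = base_win + rng.uniform(0.005, 0.010, n_win)
    base_loss = rng.uniform(0.50, 0.90, n - n_win)
    t_loss = base_loss - rng.uniform(0.20, 0.30, n - n_win)
    target = np.concatenate([t_win, t_loss])
    paralog = np.concatenate([base_win, base_loss])
    order = rng.permutation(n)
    return _score_set(target[order], paralog[order])
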