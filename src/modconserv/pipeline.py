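"""End-to-end orchestration: align pairs → enumerate sites → score columns
→ window statistics → hypothesis tests → BH adjustment → TSV/CSV export.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .alignments import ModificationRecord, ParalogPair, StrainAlignment, StrainTree
from .conservation import ALGORITHMS, ConservationProfile, ScoringConfig, score_profile
from .pairs import SiteOfInterest, find_sites_of_interest
from .stats import (
    DegenerateDataError,
    TestResult,
    adjust_results,
    paired_wilcoxon_greater,
    paralog_pairing_test,
)
from .windows import ALL_STATISTICS, SYMMETRIC_STATS, build_paired_sets

logger = logging.getLogger(__name__)

MOD_TYPES_ORDER = (
    "phosphorylation", "ubiquitylation", "monoacetylation",
    "N-glycosylation", "succinylation",
)


@dataclass
class PipelineConfig:
    algorithms: Sequence[str] = ("shannon",)
    statistics: Sequence[str] = SYMMETRIC_STATS
    gap_penalty: bool = False
    pairing_B: int = 10_000
    seed: int = 0
    tree: StrainTree | None = None
    reference_strain: str = "S288C"
    # BH families: results are adjusted within each (test, algorithm) family
    # across all statistic × modification cells, mirroring one heatmap panel.
    bh_family: str = "test_algorithm"

    def __post_init__(self) -> None:
        for alg in self.algorithms:
            if alg not in ALGORITHMS:
                raise ValueError(f"unknown algorithm {alg!r}")
        for stat in self.statistics:
            if stat not in ALL_STATISTICS:
                raise ValueError(f"unknown statistic {stat!r}")


@dataclass
class AnalysisBundle:
    sites: list[SiteOfInterest]
    profiles: dict[tuple[str, str], ConservationProfile]   # (algorithm, orf)
    results: list[TestResult]
    dropped_pairs: dict[tuple[str, str, str], int] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for r in self.results:
            rows.append({
                "test": r.test_name,
                "algorithm": r.metadata.get("algorithm"),
                "statistic": r.metadata.get("statistic"),
                "mod_type": r.metadata.get("mod_type"),
                "stat_value": r.statistic,
                "p_value": r.p_value,
                "adjusted_p": r.adjusted_p,
                "n": r.n,
            })
        return pd.DataFrame(rows)

    def matrix(self, test: str, algorithm: str) -> pd.DataFrame:
        """Adjusted-p matrix (rows = window statistic, cols = modification)."""
        df = self.to_frame()
        sub = df[(df["test"] == test) & (df["algorithm"] == algorithm)]
        return sub.pivot_table(index="statistic", columns="mod_type",
                               values="adjusted_p", aggfunc="first")


def run_full_analysis(
    alignments: Mapping[str, StrainAlignment],
    pairs: Iterable[ParalogPair],
    mods: Iterable[ModificationRecord],
    config: PipelineConfig,
) -> AnalysisBundle:
    """Run the complete paired-site conservation analysis on loaded inputs."""
    pairs = list(pairs)
    mods = list(mods)
    sequences = {orf: aln.reference_sequence for orf, aln in alignments.items()}
    sites = find_sites_of_interest(pairs, mods, sequences)
    logger.info("found %d sites of interest across %d pairs", len(sites), len(pairs))

    needed_orfs = sorted({o for s in sites for o in (s.target_orf, s.paralog_orf)})
    profiles: dict[tuple[str, str], ConservationProfile] = {}
    for alg in config.algorithms:
        sc = ScoringConfig(
            algorithm=alg, gap_penalty=config.gap_penalty,
            reference_strain=config.reference_strain, tree=config.tree,
        )
        for orf in needed_orfs:
            profiles[(alg, orf)] = score_profile(alignments[orf], sc)

    results: list[TestResult] = []
    dropped: dict[tuple[str, str, str], int] = {}
    for alg in config.algorithms:
        per_alg = {orf: profiles[(alg, orf)] for orf in needed_orfs}
        family_mean: list[TestResult] = []
        family_pairing: list[TestResult] = []
        for stat in config.statistics:
            by_mod = build_paired_sets(sites, per_alg, alg, stat)
            for mod in sorted(by_mod, key=lambda m: MOD_TYPES_ORDER.index(m)
                              if m in MOD_TYPES_ORDER else 99):
                pset = by_mod[mod]
                dropped[(alg, stat, mod)] = pset.n_dropped
                if len(pset) < 2:
                    continue
                try:
                    family_mean.append(paired_wilcoxon_greater(pset))
                except DegenerateDataError:
                    pass
                family_pairing.append(
                    paralog_pairing_test(pset, B=config.pairing_B, seed=config.seed)
                )
        results.extend(adjust_results(family_mean))
        results.extend(adjust_results(family_pairing))

    return AnalysisBundle(sites=sites, profiles=profiles, results=results,
                          dropped_pairs=dropped)


def export_bundle(bundle: AnalysisBundle, outdir: str | Path,
                  config: PipelineConfig) -> None:
    """Write the long-format results TSV and one adjusted-p matrix per
    (test, algorithm) panel."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    df = bundle.to_frame()
    df.to_csv(outdir / "test_results.tsv", sep="\t", index=False)
    sites_rows = [{
        "orf_a": s.pair.orf_a, "orf_b": s.pair.orf_b, "target_orf": s.target_orf,
        "mod_type": s.mod_type, "residue": s.residue,
        "target_position": s.target_position,
        "paralog_position": s.paralog_position,
    } for s in bundle.sites]
    pd.DataFrame(sites_rows).to_csv(outdir / "sites_of_interest.tsv",
                                    sep="\t", index=False)
    for test in df["test"].dropna().unique():
        for alg in df["algorithm"].dropna().unique():
            mat = bundle.matrix(test, alg)
            if not mat.empty:
                mat.to_csv(outdir / f"matrix_{test}_{alg}.csv")
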