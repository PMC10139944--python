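"""Windowed conservation statistics around sites of interest.

Three families of window averages over a protein's per-position conservation
profile, all in ungapped reference coordinates of that protein:

* symmetric: mean1..mean4 — site ± k residues (3, 5, 7, 9 positions);
* one-sided: meanb1..meanb4 / meana1..meana4 — the site plus k residues
  strictly before / after it (k+1 positions);
* chemical-similarity: chem_b1 / chem_a1 — the site plus its immediate
  neighbour, stratified by the neighbour's chemical class.

Windows are clipped at the sequence termini and the mean runs over the
positions that exist; per-position nan scores are skipped.  A window with
no defined score yields nan.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np

from ._tables import CHEMICAL_CLASS_OF
from .conservation import ConservationProfile
from .pairs import SiteOfInterest

SYMMETRIC_STATS = ("mean1", "mean2", "mean3", "mean4")
BEFORE_STATS = ("meanb1", "meanb2", "meanb3", "meanb4")
AFTER_STATS = ("meana1", "meana2", "meana3", "meana4")
CHEM_STATS = ("chem_b1", "chem_a1")
ALL_STATISTICS = SYMMETRIC_STATS + BEFORE_STATS + AFTER_STATS + CHEM_STATS


class MissingProfileError(KeyError):
    pass


def _window_mean(profile: ConservationProfile, lo: int, hi: int) -> float:
    """Mean of defined scores at 1-based positions lo..hi, clipped."""
    n = len(profile.by_position)
    lo, hi = max(1, lo), min(n, hi)
    if lo > hi:
        return float("nan")
    window = profile.by_position[lo - 1:hi]
    if np.all(np.isnan(window)):
        return float("nan")
    return float(np.nanmean(window))


def symmetric_mean(profile: ConservationProfile, position: int, k: int) -> float:
    """Mean over site ± k residues (2k+1 positions at an interior site)."""
    if not 1 <= k <= 4:
        raise ValueError("k must be in 1..4")
    return _window_mean(profile, position - k, position + k)


def one_sided_mean(profile: ConservationProfile, position: int,
                   direction: str, k: int) -> float:
    """Mean over the site and the k residues before or after it."""
    if not 1 <= k <= 4:
        raise ValueError("k must be in 1..4")
    if direction == "before":
        return _window_mean(profile, position - k, position)
    if direction == "after":
        return _window_mean(profile, position, position + k)
    raise ValueError(f"direction must be 'before' or 'after', got {direction!r}")


def chemical_class_of(residue: str) -> str:
    """Chemical class of a standard amino acid (five-way partition)."""
    try:
        return CHEMICAL_CLASS_OF[residue]
    except KeyError:
        raise ValueError(f"cannot classify nonstandard symbol {residue!r}") from None


def chemical_similarity_mean(profile: ConservationProfile, position: int,
                             direction: str) -> tuple[str, float] | None:
    """Mean of the site score and its adjacent neighbour's, with the
    neighbour's chemical class.  Returns None at a terminal site."""
    neighbor = position - 1 if direction == "before" else position + 1
    if direction not in ("before", "after"):
        raise ValueError(f"direction must be 'before' or 'after', got {direction!r}")
    if not 1 <= neighbor <= len(profile.reference_sequence):
        return None
    cls = chemical_class_of(profile.reference_sequence[neighbor - 1])
    lo, hi = sorted((position, neighbor))
    return cls, _window_mean(profile, lo, hi)


def window_statistic(profile: ConservationProfile, position: int,
                     statistic: str) -> tuple[float, str | None]:
    """Evaluate any named window statistic; returns (value, chem_class)."""
    if statistic in SYMMETRIC_STATS:
        return symmetric_mean(profile, position, int(statistic[-1])), None
    if statistic in BEFORE_STATS:
        return one_sided_mean(profile, position, "before", int(statistic[-1])), None
    if statistic in AFTER_STATS:
        return one_sided_mean(profile, position, "after", int(statistic[-1])), None
    if statistic in CHEM_STATS:
        direction = "before" if statistic == "chem_b1" else "after"
        res = chemical_similarity_mean(profile, position, direction)
        if res is None:
            return float("nan"), None
        return res[1], res[0]
    raise ValueError(f"unknown statistic {statistic!r}")


@dataclass(frozen=True)
class ScorePair:
    site: SiteOfInterest
    target_value: float
    paralog_value: float
    target_chem_class: str | None = None
    paralog_chem_class: str | None = None


@dataclass
class PairedScoreSet:
    """Matched (target, paralog) window scores for one modification type."""

    mod_type: str
    algorithm: str
    statistic: str
    pairs: list[ScorePair]
    n_dropped: int = 0

    @property
    def target_values(self) -> np.ndarray:
        return np.array([p.target_value for p in self.pairs])

    @property
    def paralog_values(self) -> np.ndarray:
        return np.array([p.paralog_value for p in self.pairs])

    def __len__(self) -> int:
        return len(self.pairs)


def build_paired_sets(
    sites: Iterable[SiteOfInterest],
    profiles: Mapping[str, ConservationProfile],
    algorithm: str,
    statistic: str,
) -> dict[str, PairedScoreSet]:
    """One PairedScoreSet per modification type.

    Pairs in which either member's window value is undefined are dropped and
    counted in ``n_dropped``.
    """
    grouped: dict[str, PairedScoreSet] = {}
    for site in sites:
        for orf in (site.target_orf, site.paralog_orf):
            if orf not in profiles:
                raise MissingProfileError(f"no profile for {orf}")
        pset = grouped.setdefault(
            site.mod_type,
            PairedScoreSet(site.mod_type, algorithm, statistic, []),
        )
        tv, tc = window_statistic(profiles[site.target_orf],
                                  site.target_position, statistic)
        pv, pc = window_statistic(profiles[site.paralog_orf],
                                  site.paralog_position, statistic)
        if np.isnan(tv) or np.isnan(pv):
            pset.n_dropped += 1
            continue
        pset.pairs.append(ScorePair(site, tv, pv, tc, pc))
    return grouped
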