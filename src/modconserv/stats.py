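"""Hypothesis tests for paired conservation scores and flanking-motif counts.

* distribution-mean test: one-sided paired Wilcoxon signed-rank on
  target − paralog window scores;
* paralog-pairing test: Monte-Carlo shuffle of the target↔paralog pairing;
  the reported frequency f is the fraction of shuffles in which the
  authentic pairing beats the shuffled one, with granularity exactly 1/B;
* positional chi-square: Pearson statistic on a 2×20 amino-acid count table
  (target row vs paralog row) with a fixed-margin Monte-Carlo p-value,
  followed by post hoc standardized residuals referred to the normal;
* background goodness-of-fit: observed counts against BLOSUM62-background
  expectations, Monte-Carlo p under multinomial resampling;
* Benjamini–Hochberg step-up adjustment for every p-value family.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from ._tables import AMINO_ACIDS, BLOSUM62_BACKGROUND
from .windows import PairedScoreSet

RELATIVE_POSITIONS = ("b4", "b3", "b2", "b1", "a1", "a2", "a3", "a4")


class DegenerateDataError(ValueError):
    pass


class InsufficientDataError(ValueError):
    pass


@dataclass
class TestResult:
    test_name: str
    statistic: float
    p_value: float
    n: int
    adjusted_p: float | None = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError(f"p-value {self.p_value} outside [0, 1]")


def paired_wilcoxon_greater(pairs: PairedScoreSet) -> TestResult:
    """One-sided paired Wilcoxon signed-rank: target scores larger.

    Zero differences are dropped (signed-rank convention); the null is
    enumerated exactly for ≤ 25 untied nonzero pairs, otherwise the
    tie-corrected normal approximation with continuity correction is used.
    """
    d = pairs.target_values - pairs.paralog_values
    d = d[d != 0.0]
    if d.size == 0:
        raise DegenerateDataError("all target-paralog differences are zero")
    untied = np.unique(np.abs(d)).size == d.size
    method = "exact" if (d.size <= 25 and untied) else "approx"
    res = sps.wilcoxon(d, alternative="greater", method=method, correction=True)
    return TestResult(
        test_name="distribution_mean",
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        n=int(d.size),
        metadata={
            "mod_type": pairs.mod_type,
            "algorithm": pairs.algorithm,
            "statistic": pairs.statistic,
            "method": method,
        },
    )


def pairing_frequency(target: np.ndarray, paralog: np.ndarray) -> float:
    """Fraction of pairs where the target score strictly exceeds the paralog's."""
    return float(np.mean(target > paralog))


def paralog_pairing_test(pairs: PairedScoreSet, B: int = 10_000,
                         seed: int = 0) -> TestResult:
    """Monte-Carlo shuffle test of the target↔paralog pairing structure.

    P_auth is the fraction of authentic pairs with target > paralog; each of
    B uniform random permutations of the paralog assignments gives a
    shuffled P_s.  f = fraction of shuffles with P_auth > P_s (granularity
    exactly 1/B); the reported p-value is 1 − f, small when the authentic
    pairing advantages the targets.
    """
    n = len(pairs)
    if n < 2:
        raise InsufficientDataError("pairing test needs at least 2 pairs")
    if B < 1:
        raise ValueError("B must be >= 1")
    rng = np.random.default_rng(seed)
    target = pairs.target_values
    paralog = pairs.paralog_values
    p_auth = pairing_frequency(target, paralog)
    wins = 0
    for _ in range(B):
        perm = rng.permutation(n)
        p_s = float(np.mean(target > paralog[perm]))
        if p_auth > p_s:
            wins += 1
    f = wins / B
    return TestResult(
        test_name="paralog_pairing",
        statistic=p_auth,
        p_value=1.0 - f,
        n=n,
        metadata={
            "mod_type": pairs.mod_type,
            "algorithm": pairs.algorithm,
            "statistic": pairs.statistic,
            "frequency": f,
            "B": B,
            "seed": seed,
        },
    )


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values, clipped to 1."""
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def adjust_results(results: Iterable[TestResult]) -> list[TestResult]:
    """BH-adjust a family of TestResults in place and return them."""
    results = list(results)
    if not results:
        return results
    adjusted = bh_adjust([r.p_value for r in results])
    for r, ap in zip(results, adjusted):
        r.adjusted_p = float(ap)
    return results


@dataclass
class PositionContingency:
    """2 × 20 amino-acid counts (target row, paralog row) at one offset."""

    relative_position: str
    target_counts: np.ndarray
    paralog_counts: np.ndarray

    def __post_init__(self) -> None:
        self.target_counts = np.asarray(self.target_counts, dtype=int)
        self.paralog_counts = np.asarray(self.paralog_counts, dtype=int)
        for row in (self.target_counts, self.paralog_counts):
            if row.shape != (20,):
                raise ValueError("each row must hold 20 amino-acid counts")
            if np.any(row < 0):
                raise ValueError("counts must be nonnegative")

    @property
    def table(self) -> np.ndarray:
        return np.vstack([self.target_counts, self.paralog_counts])


def _pearson_statistic(table: np.ndarray) -> float:
    rowsums = table.sum(axis=1, keepdims=True)
    colsums = table.sum(axis=0, keepdims=True)
    expected = rowsums * colsums / table.sum()
    with np.errstate(invalid="ignore", divide="ignore"):
        terms = (table - expected) ** 2 / expected
    return float(np.nansum(terms))


def chi_square_motif_test(contingency: PositionContingency, B: int = 10_000,
                          seed: int = 0) -> TestResult:
    """Pearson chi-square on the 2×20 table with fixed-margin Monte-Carlo p.

    Columns empty in both rows are dropped.  Replicate tables with both
    margins fixed are drawn via the multivariate hypergeometric (the two-row
    equivalent of R's r2dtable); p = (1 + #{X²_sim ≥ X²_obs}) / (B + 1).
    """
    table = contingency.table
    if np.any(table.sum(axis=1) == 0):
        raise DegenerateDataError("a contingency row is all zeros")
    keep = table.sum(axis=0) > 0
    table = table[:, keep]
    x2 = _pearson_statistic(table)
    rng = np.random.default_rng(seed)
    n1 = int(table[0].sum())
    colsums = table.sum(axis=0)
    exceed = 0
    for _ in range(B):
        row1 = rng.multivariate_hypergeometric(colsums, n1)
        sim = np.vstack([row1, colsums - row1])
        if _pearson_statistic(sim) >= x2 - 1e-12:
            exceed += 1
    return TestResult(
        test_name="chi_square_motif",
        statistic=x2,
        p_value=(1 + exceed) / (B + 1),
        n=int(table.sum()),
        metadata={"relative_position": contingency.relative_position,
                  "B": B, "seed": seed},
    )


def posthoc_residuals(contingency: PositionContingency) -> list[TestResult]:
    """Per-cell standardized residuals with two-sided normal p and BH.

    r_ij = (O−E)/sqrt(E·(1−row/N)·(1−col/N)); the recorded direction is
    'Target > Paralog' when the target-row residual is positive.  Cells with
    zero expectation are skipped and flagged; BH runs across retained cells.
    """
    table = contingency.table.astype(float)
    N = table.sum()
    rowsums = table.sum(axis=1)
    colsums = table.sum(axis=0)
    expected = np.outer(rowsums, colsums) / N
    results: list[TestResult] = []
    for j, aa in enumerate(AMINO_ACIDS):
        for i, role in enumerate(("target", "paralog")):
            denom = expected[i, j] * (1 - rowsums[i] / N) * (1 - colsums[j] / N)
            if denom <= 0:
                continue
            r = (table[i, j] - expected[i, j]) / np.sqrt(denom)
            p = 2.0 * sps.norm.sf(abs(r))
            if role == "target":
                direction = "Target > Paralog" if r > 0 else "Target < Paralog"
            else:
                direction = "Target < Paralog" if r > 0 else "Target > Paralog"
            results.append(
                TestResult(
                    test_name="posthoc_residual",
                    statistic=float(r),
                    p_value=min(1.0, float(p)),
                    n=int(N),
                    metadata={
                        "relative_position": contingency.relative_position,
                        "amino_acid": aa,
                        "row": role,
                        "direction": direction,
                    },
                )
            )
    return adjust_results(results)


def blosum_background_test(observed: np.ndarray,
                           background: np.ndarray | None = None,
                           B: int = 10_000, seed: int = 0) -> TestResult:
    """Goodness-of-fit of observed amino-acid counts to the background.

    Expected counts are N × background (background floored at 1e-6 and
    renormalized); Monte-Carlo p by multinomial resampling under the
    background.
    """
    observed = np.asarray(observed, dtype=float)
    if observed.shape != (20,):
        raise ValueError("observed must hold 20 amino-acid counts")
    N = observed.sum()
    if N < 1:
        raise InsufficientDataError("no observed counts")
    q = BLOSUM62_BACKGROUND if background is None else np.asarray(background, float)
    q = np.maximum(q, 1e-6)
    q = q / q.sum()
    expected = N * q
    x2 = float(((observed - expected) ** 2 / expected).sum())
    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(B):
        sim = rng.multinomial(int(N), q)
        x2_sim = float(((sim - expected) ** 2 / expected).sum())
        if x2_sim >= x2 - 1e-12:
            exceed += 1
    return TestResult(
        test_name="background_goodness_of_fit",
        statistic=x2,
        p_value=(1 + exceed) / (B + 1),
        n=int(N),
        metadata={"B": B, "seed": seed},
    )


def build_position_contingency(
    sites: Iterable,
    sequences: Mapping[str, str],
    relative_position: str,
) -> PositionContingency:
    """Tally the amino acid at site+offset in targets and mapped paralogs.

    ``relative_position`` is one of b4..b1, a1..a4 (b = upstream, a =
    downstream of the site).  Sites whose offset falls outside either
    sequence are skipped.
    """
    if relative_position not in RELATIVE_POSITIONS:
        raise ValueError(f"unknown relative position {relative_position!r}")
    k = int(relative_position[1])
    offset = -k if relative_position[0] == "b" else k
    target_counts = np.zeros(20, dtype=int)
    paralog_counts = np.zeros(20, dtype=int)
    aa_index = {aa: i for i, aa in enumerate(AMINO_ACIDS)}
    for site in sites:
        tseq = sequences[site.target_orf]
        pseq = sequences[site.paralog_orf]
        tpos = site.target_position + offset
        ppos = site.paralog_position + offset
        if not (1 <= tpos <= len(tseq) and 1 <= ppos <= len(pseq)):
            continue
        ta, pa = tseq[tpos - 1], pseq[ppos - 1]
        if ta not in aa_index or pa not in aa_index:
            continue
        target_counts[aa_index[ta]] += 1
        paralog_counts[aa_index[pa]] += 1
    return PositionContingency(relative_position, target_counts, paralog_counts)
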