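# Methods

## Data model and coordinates

A `StrainAlignment` holds N aligned residue strings (one per strain) of
common length L for one ORF, with a designated reference strain.  All
residue positions in tables and results are 1-based indices into the
*ungapped* reference protein; alignment columns are 1-based too.  The map
between the two is built by counting non-gap reference symbols and cached on
the alignment.  Gap symbols are `-` plus the ambiguity codes `X B Z`
throughout: they are excluded from score frequencies and counted by the gap
penalty.  A residue stated in a modification table that conflicts with the
reference sequence raises by default; duplicate strain identifiers in one
FASTA are rejected.

## Conservation scores

All five scores live on [0, 1] with 1 = perfectly conserved and 0 = random.
Entropies use the natural log and are normalized by the log of the alphabet
size — log 20 for residues, log 9 for the stereochemical groups
(`VLIM | FWY | ST | NQ | HKR | DE | AG | P | C`) — which makes the scores
base-invariant.  Note the two entropy scores are **not** mutually ordered:
grouping can only lower the raw entropy, but the different normalizers mean
the stereochemical score may be smaller than the Shannon score on mixed
columns.  The invariant the tests assert is the raw-entropy coarsening
inequality.

The Jensen–Shannon score uses λ = ½ and divides by log 2, its maximum, so a
column identical to the background scores 0 and maximal divergence scores 1.
The background is the BLOSUM62 amino-acid frequency vector (the marginal
distribution the matrix was derived against), packaged as a constant and
renormalized to sum exactly 1; any 20-vector can be substituted.

The phylogeny-aware score is a deliberate stand-in: the published "zoom"
weighting is not restated in the literature we implement from, so we use
`1 − Σ wᵢ·1[aᵢ ≠ a_ref] / Σ wᵢ` over non-gap comparison strains with
`wᵢ = 1/(dᵢ + ε)`, `dᵢ` the patristic distance to the reference and
`ε = 10⁻⁶ × (tree diameter)` (configurable).  This satisfies the properties
the original is described by: 1 on monomorphic columns, heavier penalties
for mismatches in strains close to the reference (strictly monotone in
mismatch distance), and reduction to the plain match fraction on a star
tree.  Columns where the reference is gapped are undefined.

The Karlin score normalizes each unordered residue pair by the geometric
mean of the diagonal entries and averages; `(s+1)/2` maps (−1, 1) to (0, 1).
Gapped rows are excluded from the pair sum rather than multiplicatively
penalized — exclusion already reduces the evidence and the matrix encodes
substitution penalties itself.  BLOSUM62 is the default matrix; PAM30 (or
any Biopython-loadable matrix) can be substituted.

Columns with no usable symbols return `nan`, never 0: a zero would
masquerade as "random" and bias window means.  Window statistics skip `nan`
positions; a window with no defined position is itself `nan` and the pair it
belongs to is dropped with a logged count.

## Pair alignment and sites of interest

Paralog reference sequences are aligned globally (Needleman–Wunsch/Gotoh)
under BLOSUM62 with the affine dialect in which a gap of length k costs
`gap_open + k·gap_extend` (defaults 10 and 0.5, so a single-residue gap
costs 10.5).  End gaps are penalized like internal ones.  Among co-optimal
alignments the traceback prefers diagonal over up over left, making the
output deterministic; the score is checked in the tests against an
exhaustive alignment-enumeration oracle and against Biopython's aligner
configured for the same dialect.

A *site of interest* is an aligned position with the identical residue in
both paralogs where exactly one member is modified for the PTM type under
study.  Substituted positions are never accepted, even conservative ones
(S↔T), and positions modified in both members are excluded — neither member
is then an unmodified partner.  The site set is invariant under swapping the
pair orientation; only the target labeling moves.

## Window statistics

Symmetric means `mean1..mean4` average the site ±k residues (3/5/7/9
positions); one-sided means `meanb·/meana·` average the site plus k residues
strictly before/after (k+1 positions); the chemical-similarity means average
the site and its immediate neighbour and are stratified by the neighbour's
chemical class (aliphatic GAVLIMP, aromatic FYW, polar uncharged STCNQ,
acidic ED, basic KRH).  Windows are defined on each protein's own ungapped
coordinates, not on pair-alignment columns.  At termini the window is
clipped and the mean runs over the available positions — no padding, which
would bias scores near sequence ends.  The site score itself is included in
every statistic.

## Statistical tests

*Distribution-mean test.*  One-sided paired Wilcoxon signed-rank on
`target − paralog`, zeros dropped.  The exact null is enumerated for ≤ 25
untied nonzero pairs; otherwise the tie-corrected normal approximation with
continuity correction (scipy's engine in both branches).

*Paralog-pairing test.*  `P_auth` is the fraction of authentic pairs with a
strict target win (ties count against the target).  Each of B unrestricted
uniform permutations of the paralog assignments (identity allowed) yields a
shuffled `P_s`; the reported frequency `f = (1/B)Σ1[P_auth > P_s]` has
granularity exactly 1/B, and the p-value is `1 − f`, small when the
authentic pairing advantages targets.  On discrete score grids the strict
inequality makes the test mildly conservative; the calibration suite uses
continuous scores.  All Monte-Carlo routines take explicit seeds and record
(B, seed) in the result metadata.

*Positional chi-square.*  Amino-acid counts at each offset b4…a4 relative to
the site form a 2×20 table (target row, paralog row); columns empty in both
rows are dropped.  The Monte-Carlo p-value resamples tables with both
margins fixed via the multivariate hypergeometric (the two-row equivalent of
r2dtable) and uses the `(1 + #{X²_sim ≥ X²_obs})/(B + 1)` estimator, which
cannot return 0.  Post hoc, standardized residuals
`(O−E)/√(E(1−row/N)(1−col/N))` get two-sided normal p-values — the direction
is recorded separately as Target > Paralog / Target < Paralog — and BH runs
across the cells of the position.  The residuals and statistic were
cross-checked against R's `chisq.test` on a frozen table.

*Background comparison.*  Flank composition is also tested against the
BLOSUM62 background by a goodness-of-fit chi-square with multinomial
Monte-Carlo p; the background is floored at 10⁻⁶ before expected counts
(all its entries are positive anyway).

*Multiplicity.*  BH step-up adjustment (statsmodels), applied within each
(test × algorithm) family across all window × modification cells — one
heatmap panel per family.  The family definition is a pipeline-config
choice.

## Synthetic data

The generator reproduces the statistical structure of the real inputs
without any download.  For each pair, both members share one reference
protein sequence (background-distributed residues with a serine forced at
every planted site) and one per-position base conservation vector
(`conservation_base` ± 0.25, clipped to [0.05, 0.95]) — paralogs share an
evolutionary history, so base conservation is a pair-level quantity.  Each
member's alignment then realizes the conservation independently: per column
each non-reference strain keeps the consensus with the requested probability
or redraws from the BLOSUM62 background.  A `flank_advantage` δ is added to
the target's conservation inside ±4 residues of each planted site.  With
δ = 0 the two members' window scores are exchangeable (the null); δ > 0
plants the alternative.  The motif generator instead tilts the target's
residue distribution at one relative position by an enrichment factor.
Strain trees are random binary topologies with exponential(0.1) branch
lengths.  Everything is driven by a single `default_rng(seed)` and
regenerates bit-identically.

Defaults: 16 strains, 60 pairs, 2 sites per pair, protein length 30,
base conservation 0.6.  What the simulations do *not* emulate: linkage
between columns, realistic yeast clade structure, gap patterns from real
indel evolution, or ascertainment bias in PTM catalogs — so passing
calibration here demonstrates the statistics behave correctly under
exchangeability and known effects, not that real data meet those
assumptions.

The three scenario fixtures realize the distribution/pairing contract:
non-overlapping distributions (mean test significant, pairing test
necessarily not — every shuffle also scores 1); overlapping marginals with a
uniform within-pair advantage (both significant); and matched, heavily
overlapping marginals whose pairing still advantages the target.  The third
is built as ~71 % narrow target wins and ~29 % large target losses: all win
magnitudes are below all loss magnitudes, so the positive signed-rank sum
sits at ≈ n(n+1)/4 (its null mean) and the Wilcoxon test stays
non-significant, while the 0.71 win fraction is far above the ≈ 0.5 shuffle
null.

## Problem sizes and numerical choices

The calibration suite runs 500 exchangeable-null replicates at 60 pairs × 2
sites, 8 strains, B = 400 shuffles, and the power experiment 60 replicates
at 100 pairs × 2 sites (200 paired values), 16 strains, δ = 0.1 — sizes
chosen to estimate rejection rates to ±0.02 while keeping the suite fast.
The exhaustive oracles run on 4-letter alphabets: all sequence pairs to
length 3 plus seeded random pairs to length 7 for the aligner, all column
multisets to size 5 for the Karlin score, and all n! pairings for n ≤ 6 for
the pairing test.

Ties in the aligner traceback resolve diagonal > up > left.  The chi-square
Monte-Carlo comparison uses a 10⁻¹² slack on `X²_sim ≥ X²_obs` to absorb
floating-point noise.  `nan` sentinels propagate through profiles and are
dropped (with counts) when paired sets are assembled.

## Known limitations

- The phylogeny-aware score is a documented stand-in, not the published
  "zoom" weighting; scores are comparable within this package only.
- PWM kinase assignment uses the raw weight sum over the −5..+4 window with
  terminal offsets skipped; log-space or percentile normalization would need
  a different convention and is left as a hook.
- The pipeline assumes one reference protein per ORF; splice isoforms and
  chain breaks are out of scope, and windows never cross them.
- Reported counts from interaction or structure databases depend on the
  snapshot consumed; this package computes the summaries, not the catalogs.
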