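# modconserv

Conservation scoring of multi-strain protein alignments, and statistics of
the sequence context of posttranslational-modification (PTM) sites in
paralogous protein pairs.

## The problem

Many budding-yeast proteins exist as paralog pairs retained from an ancient
whole-genome duplication.  The two members often carry different chemical
modifications (phosphorylation, ubiquitylation, acetylation, …) even at
positions where the amino acid itself is identical.  A natural question for
molecular evolutionists: is the sequence *around* a modified site more
conserved across strains than the corresponding region of the unmodified
paralog?  Answering it needs (i) per-column conservation scores over a deep
within-species alignment, (ii) a coordinate map between the two paralogs,
and (iii) paired statistics that respect the pairing structure of the data.

`modconserv` provides all three, plus a synthetic-data generator that
reproduces the statistical structure of such datasets for testing and
calibration.

## What it computes

**Five per-column conservation scores**, each normalized to [0, 1]
(1 = perfectly conserved, 0 = random), for an alignment of N strains:

- Shannon: `1 − H(p)/log 20` over the residues of the column;
- stereochemical entropy: the same with residues coarsened into 9
  physicochemical groups (`1 − H(g)/log 9`);
- Jensen–Shannon divergence from the BLOSUM62 background distribution,
  normalized by its log 2 maximum — large when selection has pulled the
  column away from the no-constraint background;
- a phylogeny-weighted mismatch score anchored at a reference strain
  (mismatches in strains close to the reference are penalized more);
- Karlin substitution-matrix normalization: the mean of
  `M(aᵢ,aⱼ)/√(M(aᵢ,aᵢ)M(aⱼ,aⱼ))` over all residue pairs, reranged from
  (−1, 1) to (0, 1).

An optional gap penalty multiplies any score by the column's non-gap
fraction (gaps are `X B Z -`); the Karlin score never receives it, since
excluding gapped rows from the pair sum is already its penalty.

**Paralog site mapping** by Needleman–Wunsch global alignment (BLOSUM62;
affine gaps where a length-k gap costs `10 + 0.5·k`), then enumeration of
*sites of interest*: positions with the identical residue in both paralogs
where exactly one member is modified for a given PTM type.

**Windowed statistics** around each site — symmetric means over the site
±1…4 residues (`mean1`…`mean4`, i.e. 3/5/7/9 positions), one-sided means
(`meanb1`…`meana4`), and chemical-similarity means of the site plus its
adjacent residue, stratified by that residue's chemical class.

**Hypothesis tests** on the matched (target, paralog) score pairs:

- *distribution-mean test*: one-sided paired Wilcoxon signed-rank;
- *paralog-pairing test*: shuffle the target↔paralog pairing B times; with
  `P_auth` the fraction of authentic pairs in which the target wins,
  `f = (1/B) Σ 1[P_auth > P_shuffle]` (granularity exactly 1/B) and
  `p = 1 − f`;
- positional chi-square on 2×20 amino-acid count tables at offsets b4…a4
  with a fixed-margin Monte-Carlo p-value and post hoc standardized
  residuals (two-sided normal p, BH-adjusted, direction recorded as
  Target > Paralog or Target < Paralog);
- goodness-of-fit of flank composition against the BLOSUM62 background;
- Benjamini–Hochberg adjustment within each (test × algorithm) family.

Annex analyses cover kinase–substrate tables (single-interaction ratio,
PWM-based kinase assignment and disjoint-kinase pairs), abundance and
multi-study filters, and secondary-structure/solvent-accessibility
differences parsed from STRIDE output.

## Worked example

Simulate a dataset in which the ±4-residue flanks of modified target sites
get +0.15 extra per-column conservation, then run the full workflow:

```sh
printf 'flank_advantage: 0.15\nn_pairs: 40\n' > adv.yaml
modconserv run-all --config adv.yaml --seed 7 --outdir demo
cat demo/matrix_distribution_mean_shannon.csv
```

```
statistic,phosphorylation
mean1,1.1441771688744005e-14
mean2,5.538705253810156e-15
mean3,5.538705253810156e-15
mean4,5.538705253810156e-15
```

```sh
cat demo/matrix_paralog_pairing_shannon.csv
```

```
statistic,phosphorylation
mean1,0.0
mean2,0.0
mean3,0.0008000000000000599
mean4,0.011099999999999999
```

Each matrix is one heatmap panel: rows are window statistics, columns are
modification types, cells are BH-adjusted p-values.  Both tests detect the
planted flanking-conservation advantage at every window size, as they
should.  Rerunning with `flank_advantage: 0` (the exchangeable null) leaves
every cell non-significant at the 5 % level in the vast majority of seeds.

Single stages are also exposed: `modconserv score` (per-column profile TSV
for one ORF), `sites`, `motif`, `test-mean`, `test-pairing`, `kinase`,
`structure`, `simulate`.

The same thing in Python:

```python
from modconserv import PipelineConfig, run_full_analysis
from modconserv.simulate import SimulationConfig, simulate_paralog_dataset

alns, pairs, mods = simulate_paralog_dataset(
    SimulationConfig(n_pairs=40, flank_advantage=0.15, seed=7))
bundle = run_full_analysis(alns, pairs, mods,
                           PipelineConfig(algorithms=("shannon",), seed=7))
print(bundle.matrix("paralog_pairing", "shannon"))
```

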