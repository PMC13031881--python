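# rloopedit

Strand-aware statistical analysis of APOBEC3B (A3B) cytosine editing at
R-loops, and of its processing into DNA double-strand breaks (DSBs).

R-loops are three-stranded structures — a DNA:RNA hybrid plus a displaced
single DNA strand — that form co-transcriptionally, prominently at
oestrogen-receptor enhancers after oestradiol (E2) stimulation.  The
displaced strand is single-stranded DNA, the substrate of the deaminase
A3B, which converts C→U preferentially in the 5'-TCW motif (W = A/T).
Repair of those lesions (BER and TC-NER acting on the same locus) can
convert edits into DSBs.  Testing this model against sequencing data needs
a set of strand-resolved statistics that are scattered across many tools;
`rloopedit` implements them as one coherent, tested Python library:

- **Mutation spectra** — pyrimidine-normalised trinucleotide
  classification, 96-channel spectra (6 substitution classes × 16 flank
  pairs), TCW/CpG annotation, intermutation distance (IMD), detection of
  clustered hypermutation (omikli: runs of 2–4 mutations with adjacent
  IMD ≤ 1 kb; kataegis: runs of ≥ 5) with a permutation null, and de novo
  signature extraction by multiplicative-update NMF under the generalised
  Kullback–Leibler divergence with cosine-similarity matching.
- **Sequence features** — windowed GC-skew `(G − C)/(G + C)` (200 bp),
  G4Hunter G-quadruplex propensity (runs capped at 4, 25 bp windows,
  |score| ≥ 1.2), and strand-aware metaprofiles with 95% confidence bands
  around anchor sets (minus-strand anchors reversed, antisymmetric tracks
  sign-flipped).
- **Interval integration** — overlap/proximity classification (± 1.5 kb),
  strand concordance of mutation pyrimidine strand with the R-loop
  displaced strand (exact binomial CI), enrichment against uniformly
  sampled random sites, chromatin-state fold enrichment, replication-timing
  quartile mutation rates, GREAT-style basal-plus-extension region→gene
  assignment, and the closed-form 2×2 χ² test.
- **Differential peaks** — ≥ k-of-n consensus construction with 1 kb
  same-strand merging, midpoint fragment counting, median-of-ratios size
  factors with composition-bias refinement, a negative-binomial Wald test
  (`log2FC / SE`, common method-of-moments dispersion, BH FDR), a
  two-factor interaction test `(l₁₁ − l₁₀) − (l₀₁ − l₀₀)`, induction calls
  at FDR ≤ 0.05 and |FC| ≥ 1.5 with an optional top-25% base-mean filter,
  and hypergeometric gene-set overlap tests.
- **DSB classification** — E2-induced vs A3B-modified break classes,
  their cross-tabulation with A3B-binding and R-loop overlap, and
  per-class knockdown dependence `log2(siA3B / NT)`.
- **Synthetic data** — a fully seeded generator that plants every one of
  these structures (GC-skewed stranded R-loops with G4 motifs, concordant
  TCW edits, clusters, induced peak counts, class-conditional DSB
  dependence) so the entire pipeline validates itself with no downloads.

## Worked example

```bash
python examples/03_sequence_features.py
```

```
G4 candidate intervals at threshold 1.2: 1857
genome-wide mean GC-skew: -0.0002
displaced-strand skew at R-loop centres: +0.795 +- 0.009 (95% CI)
skew in distal flanks (+-2 kb):          +0.003
(centre ~ +0.8 = planted Bernoulli(0.9) skew; flanks ~ 0 = background)
G4 density at centres vs flanks: 0.99 vs 0.29 intervals/bin
```

The generator writes strong (G/C) positions inside each R-loop as G on the
displaced strand with probability 0.9, so the expected displaced-strand
skew is (0.9 − 0.1)/(0.9 + 0.1) = +0.8; the strand-aware profile recovers
+0.795 with a ±0.009 confidence band, flat background outside.  The other
examples cover the fixture (`01`), spectra/clusters/NMF (`02`), strand
concordance and enrichment statistics (`04`), differential peaks (`05`)
and DSB classification (`06`), each printing the planted value next to the
recovered one.

A full pipeline run (simulate → spectra → features → integrate →
diffpeaks → dsb → report) is available from the shell:

```bash
rloopedit run --seed 1 --out my_run     # ~3 s on one CPU, fully seeded
```

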