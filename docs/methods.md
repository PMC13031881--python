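# Methods

This note documents the models, conventions and numerical choices behind
`rloopedit`, in the spirit of a statistical methods appendix.  Nothing here
states an empirical result that the test suite or `scripts/acceptance.py`
does not itself compute.

## Coordinate and strand conventions

All coordinates are 0-based half-open in memory and on disk (BED,
bedGraph); VCF is converted at a single boundary (`mutations.py`), which
is property-tested.  The strand column of a stranded R-loop record names
the **displaced** single-stranded DNA strand.  Because strand-specific
DRIP-style protocols differ in whether "(+) strand R-loop" denotes the
hybridised or the displaced DNA strand, `strand_concordance` and the
pipeline expose `rloop_strand_means = displaced | hybrid`; the `hybrid`
setting flips the comparison rather than guessing a convention.

## Mutation spectra and clusters

Substitutions are normalised to the pyrimidine convention (purine
references reverse-complemented with their trinucleotide context); the 96
channels follow the conventional order (C>A, C>G, C>T, T>A, T>C, T>G ×
16 flank pairs).  `is_tcw` marks the APOBEC hotspot T[C>N]A/T[C>N]T;
`is_cpg` marks a C centre followed by G.  Spectra conserve counts by
construction and are invariant under genome-wide reverse complement.

Clusters are maximal runs of consecutive same-sample mutations on one
contig with adjacent intermutation distances ≤ `d_max` (default 1000 bp,
the short-distance regime used to separate clustered from dispersed
mutations).  Runs of 2–4 are called omikli, ≥ 5 kataegis; this transparent
adjacency rule replaces heavier clustering machinery, and the 2–4 boundary
is a documented approximation of "small fog-like clusters" versus larger
foci.  Per-sample significance is empirical:
`p = (1 + #{permutations with ≥ observed cluster count}) / (1 + n_perm)`,
with positions re-drawn uniformly within the callable regions.  The
cluster *count* is non-monotone in clustering strength at very high
mutation density (dense runs merge), so the test is meaningful for diffuse
mutation sets and is conservative under the uniform null.

Signature extraction is multiplicative-update NMF minimising generalised
KL divergence: 200 iterations maximum, relative-change tolerance 1e-6,
20 seeded restarts by default, best final divergence wins (ties broken by
lowest restart index), signature columns normalised to sum one with
exposures rescaled.  The objective is non-increasing per iteration, which
the tests assert; scikit-learn's KL-NMF serves as an independent
cross-check, never as the implementation.

## Sequence features

GC-skew is `(G − C)/(G + C)` per 200 bp window on the + strand, the −
strand being its negation; windows without G or C are missing, and missing
bins are excluded (not imputed) everywhere downstream.  G4Hunter scores
each base by its homopolymer run: G runs of length L score `+min(L, 4)`
per base, C runs the negative, others 0; a window's score is the
arithmetic mean, and the scan merges same-sign qualifying 25 bp windows
(|mean| ≥ 1.2) whose extents overlap or abut, recording G-rich as `+` and
C-rich as `-`.  Run-capping at 4 and the 25 bp window follow the original
algorithm; the scan threshold 1.2 and the 100 bp density bin are the
analysis settings.  The density track counts overlapping G4 intervals per
bin (base coverage per bin would be an alternative reading of "G4
frequency"; interval counts are implemented and documented).

Metaprofiles aggregate genome-aligned track bins around anchor midpoints:
mean, `ci95 = 1.96 × SEM` and per-position `n`.  With `strand_aware`,
minus-strand anchor windows are reversed; with `antisymmetric` (GC-skew)
they are also sign-flipped.  Bins are left-aligned and genome-anchored, so
the bin containing an anchor midpoint can sit up to one bin width off
centre; profiles over features shorter than ~4 bins therefore dilute edge
positions with outside sequence, which is why the synthetic R-loops
default to ≥ 800 bp (see below).

## Interval statistics

Proximity: overlapping means ≥ 1 bp intersection; proximal means an
end-to-end gap ≤ d (default 1500 bp, i.e. ± 1.5 kb); the boundary is
inclusive and ties in nearest-reference queries resolve to the leftmost.
Strand concordance uses mutations inside exactly one R-loop (double
opposite-strand overlaps are excluded and counted) and reports the exact
Clopper–Pearson 95% CI; the accompanying 2×2 contrast compares
inside-R-loop mutations with outside mutations matched to their nearest
R-loop's strand, because mutations outside an R-loop have no displaced
strand of their own.  Random sites are drawn by inverse CDF over the
allowed-segment cumulative lengths — exact, seeded, and failing loudly
when the exclusion covers the genome.  State enrichment is
`(target bases in state / target bases) / (state bases / genome bases)`;
point targets are expanded ± flank (default 200 bp, with the narrower
± 50 bp variant available via configuration).  Replication-timing
quartiles split covered bins by value with a stable (value, contig, bin)
tie-break, Q1 = latest replicating; rates are mutations per covered Mb
normalised to Q1.  Region→gene assignment is GREAT-style
basal-plus-extension: basal −5000/+1000 bp around the TSS (strand-aware),
extended to the nearest neighbouring basal edge and capped at 1 Mb from
the TSS.

## Differential testing

Size factors are DESeq-style median-of-ratios over features with positive
counts in every sample.  Because one-directional occupancy changes drag
the per-feature geometric-mean reference, the estimator is refined:
differential (or four-cell, for the interaction design) passes mark
features with |fold change| ≥ 1.5 and the factors are re-estimated on the
stable remainder until the stable set converges (≤ 10 passes).  Only
factor *ratios* are identified; the overall scale follows the
geometric-mean reference, exactly as in DESeq2.

The test itself is one transparent negative-binomial Wald scheme, not an
emulation of DESeq2 or edgeR: per-feature normalised group means, a
**common** method-of-moments dispersion pooled across groups *and*
features — `α̂ = max(Σ(s² − μ̂)/Σμ̂², 0.01)` — and the delta-method
variance `Var(ln μ̂) ≈ (1/n)(1/μ̂ + α̂)` per group, giving
`z = log2FC / SE` against the normal, BH-adjusted.  Pooling the dispersion
across features is what keeps the statistic calibrated at 2–3 replicates:
per-feature variance estimates at ~4 degrees of freedom make a
normal-referenced Wald statistic heavy-tailed, which the null-calibration
test would (and, during development, did) detect.  The price is
insensitivity to genuine dispersion heterogeneity across features —
acceptable for the homogeneous-dispersion counts this package targets,
and stated here as a limitation.  A 0.5 pseudocount stabilises logs of
near-zero group means; features with all-zero groups get p = 1 and
log2FC = 0, flagged.  The interaction estimate is
`(l₁₁ − l₁₀) − (l₀₁ − l₀₀)` with variance summed over the four cells.

Induction calls use inclusive thresholds (FDR ≤ 0.05, linear |FC| ≥ 1.5).
The optional top-quarter base-mean filter re-runs BH on the retained
subset (filter-then-adjust, the order quantitative peak pipelines use);
the filter trades sensitivity on low-abundance features for a smaller
testing burden, and both modes are exposed.

The per-class DSB dependence contrast (A3B-and-R-loop class versus the
rest) is a feature-level comparison, not a sample-level factor, so it is
tested with Welch's t on the per-feature log2 ratios alongside the
per-feature genotype Wald table; the sample-level E2 × knockdown design
uses the interaction test proper.

## Synthetic data: what it emulates and what it does not

The generator plants, under one master seed with named independent
sub-streams (byte-identical bundles per config):

- a background genome of i.i.d. bases at GC 0.41 (human-like);
- 200 non-overlapping R-loops of 800–1600 bp (rejection-sampled, ≤ 1000
  retries, loud failure when overcrowded), strand Bernoulli(0.5); inside
  each, strong positions are G on the displaced strand with probability
  0.9 (expected skew +0.8), and a (G₃N)₄ motif is written at the 5' end of
  the displaced strand with probability 0.8;
- 1000 TCW C>T mutations in R-loops with concordance 0.8 (binomially
  realised), 300 uniform background mutations, and 10 clusters of 3
  mutations evenly spaced over 900 bp, kept > 1.5 kb from all other
  mutations so planted-cluster recovery is exact;
- 3 vs 3 replicate NB counts (mean 50, dispersion 0.1, log-normal size
  factors) with 20% of features induced 3-fold;
- A3B peaks (half inside R-loops) and 400 DSB peaks in four placement
  classes; a full 2×2 (DMSO/E2 × NT/siA3B) count design in which E2
  induces 30% of DSBs 3-fold and the knockdown scales A3B∩R-loop peaks by
  0.4 under E2 only — so the dependence appears both as a knockdown
  contrast and as a negative interaction;
- a smooth sinusoidal replication-timing surrogate and a random
  chromatin-state partition with exponential segment lengths.

Where effect sizes are not externally constrained, these defaults were
chosen once for statistical power at desk scale and are not tuned
afterwards.  The generator does **not** simulate raw reads, mapping
artefacts, duplicate structure, library biases or transcript structure;
passing tests demonstrate that the statistics recover planted structure
under their own model assumptions, not that real libraries are free of
the biases upstream tools handle.  Background mutations avoid R-loops so
the concordance measurement is uncontaminated; accidental background
mutation pairs within 1 kb do occur (realistically) and are counted as
clusters alongside the planted ones.  An E2-induced fraction of 30% keeps
the majority of features stable, which normalisation identifiability
requires; at much higher changed fractions no reference-free size-factor
estimator is identified.

## Problem sizes

The default conditions run end-to-end in seconds on one CPU: a 1 Mb
two-contig genome, 1330 mutations, 2000-feature calibration matrices, 400
DSB peaks, 200 permutations for cluster nulls.  These sizes give the
planted-parameter recoveries useful precision (binomial CI half-width
~0.025 on concordance at n = 1000; SEM ~0.005 on the skew plateau at 200
anchors) while keeping the whole validation suite fast.

## Known limitations

- The common-dispersion NB test is miscalibrated when dispersion varies
  strongly across features; a trended or empirical-Bayes estimator is the
  natural extension.
- The cluster permutation test uses the cluster count, which loses power
  (and monotonicity) at saturating mutation density.
- The consequence-category annotator is a priority rule over interval
  sets, not a transcript-aware effect predictor.
- GREAT's binomial genomic-coverage test is out of scope; only the
  association rule is implemented, with hypergeometric gene-set overlap
  downstream.
- `bigWig`/BAM binary I/O is deliberately absent: bedGraph, BED, VCF and
  TSV cover desk-scale work and keep every artefact diffable.
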