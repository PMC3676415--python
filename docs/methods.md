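# Methods

## Problem setting

Small-sample, high-dimensional two-condition designs (here: rice root
tissue, control vs salt stress, 3 tolerant genotypes × 3 replicates per
condition = 18 arrays against tens of thousands of probes) make univariate
selection noisy and fold-change heuristics unreliable. The workflow treats
the three genotypes as one class per condition — pooling them mines the
pattern common to tolerant material and triples the effective sample size —
and augments the t-test axis of a volcano plot with a multivariate
stability score.

## Gene scoring

**Welch t-test.** Per probe, two-sided, unequal variances (the two
conditions have no reason to share a variance). The sign convention is
control (+1) minus stressed (−1). Probes constant in both classes with
equal means report t = 0, p = 1 — "no evidence" rather than undefined.

**SVM-RFE.** A linear soft-margin SVM (C = 1) is trained on the surviving
features, features are scored by squared weight, and the lowest-scoring 10%
(at least one) are eliminated per round; elimination order reversed gives
ranks (1 = most informative). Features are standardized to zero mean / unit
variance on the training subset; a zero-variance feature gets weight 0 and
leaves first. Ties eliminate the higher row index first, making ranks
deterministic. Chunked (10%/round) elimination rather than one-at-a-time is
a runtime choice: it changes ranks only within chunks, and MergeValue
averages over bootstraps anyway.

**MergeValue.** `B` class-stratified bootstrap resamples (with replacement,
preserving the 9/9 class split; replicate *b* uses seed `seed + b`) are
each ranked by SVM-RFE, and probe *g* scores the mean normalized reverse
rank `(G − r_gb)/(G − 1)` across replicates. The score lives in [0, 1]: a
probe eliminated last every time scores 1, first every time scores 0, and
an uninformative probe drifts to ≈ 0.5 (its expected rank is (G+1)/2) —
which makes the published threshold of 0.5 the natural "better than
indifferent" midpoint. `B` defaults to 50 in the library; the pipeline and
analysis scripts use B = 20, which is where the ranking stabilizes at the
desk scale while keeping a full run under half a minute.

**Selection.** `p ≤ 0.05` and `MergeValue ≥ 0.5`, both inclusive.

## QTL validation

Coordinates are 1-based inclusive everywhere at the interface (the
convention of the curated QTL tables and annotation releases); one audited
function converts to half-open for overlap arithmetic. Identical intervals
(same chromosome, start, end) are collapsed before counting so repeated
database entries never double-count coverage — the packaged rice
salt-tolerance table collapses 17 entries to 13. Extension flanks an
interval by one interval length per side (unclipped extended length 3L,
clipped to [1, chromosome length]). A gene hits an interval on ≥ 1 bp
overlap of its body (any-overlap: a boundary-straddling gene is evidence,
not an artifact). The Microarray-QTL statistic is the hypergeometric upper
tail P(K ≥ k) with population N (valid genes only — probes without
coordinates are excluded), successes m (genes covered by the merged
intervals), draws n (selected genes), observed k. The same machinery with a
term→gene map and Benjamini–Hochberg step-up gives generic term enrichment.

## Network modules

Isoform identifiers (`LOC_…g….<n>`) merge to locus level; self-loops from
isoform pairs and parallel edges collapse. A module is a connected
component with ≥ 2 nodes of the subnetwork induced by the selected loci
(isolated selected loci are reported separately). Components are used
because they are deterministic and parameter-free, and the published
module censuses are consistent with dense disconnected components; modules
are sorted by node count, then edge count, then smallest member id. QTL
annotation attaches per-module hit lists (original ⊆ extended by
construction); the "≥ 1 extended hit" flag is reported but never used to
drop a module. Hubs are within-module degrees, ties broken
lexicographically.

## Motifs

Promoters are the 1,000 bp upstream of the translation start, strand
oriented (minus-strand genes take the reverse complement of the downstream
flank), truncated with a flag at chromosome edges. Scanning is exact IUPAC
consensus matching, overlapping occurrences counted, forward strand only —
the promoter is already strand-oriented by extraction — and an `N` in a
sequence never matches. This replaces a PWM scanner deliberately: the
workflow's motif evidence is a consensus string, and exact degenerate-set
matching keeps the null tractable. Presence (≥ 1 occurrence) in target vs
background sets forms a 2×2 table tested by Pearson chi-square (1 df, no
continuity correction) with a warning flag when any expected cell < 5.
Motif-vs-reference comparison slides one consensus over the other ungapped;
a position matches when the IUPAC sets intersect and at least one letter is
unambiguous (two degenerate letters agreeing is weak evidence and does not
count); identity requires score > 4 matched positions and > 80% of the
shorter motif matched.

## Co-expression

Within-module coherence is the mean Pearson r over all unordered member
pairs, computed across all samples jointly (conditions pooled, matching the
single published summary number). The contrast draws seeded size-matched
random gene sets and records the mean cross-correlation between module and
draw; `empirical_p = (1 + #{cross ≥ within}) / (n_random + 1)`. Because the
observed statistic (within-set) and the reference draws (cross-set) are
different statistics, this empirical p is a descriptive contrast, not a
calibrated test: under a pure-noise null it centres near 0.5 but is
over-dispersed relative to uniform (verified by simulation in the test
suite). `n_random` defaults to 1,000.

## Synthetic data

The generators are pure functions of their configs (same seed → identical
output) and emulate the study's structure, not its biology:

- **Expression**: baselines uniform on [4, 12] log2 units; i.i.d. Gaussian
  noise (sd 1.0); informative probes shift the stressed-class mean by
  `effect_size × noise_sd` (default 2); each (probe, genotype) pair adds a
  Gaussian offset of 0.2 × noise_sd so pooling genotypes is exercised.
  Default scale 2,000 probes / 100 informative / 18 samples — a 1/30-scale
  stand-in for a ~57k-probe array. No distributional claim is inherited
  from real arrays; probe-level effects, correlated noise and
  intensity-dependent variance are all absent, so passing recovery tests
  demonstrates the selection machinery, not array realism.
- **Genome/QTLs**: 4 chromosomes × 2 Mb, 1-kb gene bodies placed uniformly,
  QTL lengths uniform in [20, 120] kb; a stated fraction (default 0.5) of
  informative genes is relocated inside QTLs so enrichment has signal by
  construction.
- **Network**: planted partition — within-module edge probability 0.6,
  cross-module 2e-4 (induced interaction subnetworks are sparse between
  functional modules, and the reference workflow's modules are disconnected
  components); a fraction (0.3) of loci is emitted as two `.1/.2` isoforms
  sharing every edge, so isoform merging reconstructs the truth graph
  exactly.
- **Promoters**: i.i.d. uniform A/C/G/T with one concrete realization of
  the planted IUPAC motif written at a uniform offset in the stated
  fraction of sequences (defaults 0.9 target / 0.2 background, 1,000 bp).

## Numerical and design notes

- Quantile normalization maps each column onto the vector of cross-column
  rank means; k-way ties receive the mean of the k rank-means they span.
  Idempotent; the equal-sorted-columns postcondition is exact for tie-free
  data. Single-column input is returned unchanged with a warning. The
  pipeline fixes the order filter-controls → normalize.
- The MergeValue definition above is this package's reconstruction of the
  bootstrap-aggregated RFE score (the original formula was not published in
  an accessible form); it was chosen because it lands in [0, 1] with 0.5 as
  the indifference point, consistent with the published threshold.
- Bootstrap, background-draw and simulation seeds all derive
  deterministically from a single global seed (stage offsets +1 … +5);
  pipeline reports contain no timestamps, so identical configs produce
  byte-identical reports.
- Degenerate inputs have declared behaviour throughout: empty matrices,
  single-class subsets, zero marginals and constant profiles raise;
  zero-variance features rank last; k = 0 gives p = 1.
- Desk-scale problem sizes (2,000 probes, B = 20, 100k permutation draws,
  1,000 calibration seeds) were chosen so the full suite and the
  reproduction script each run in minutes on one CPU.

## Limitations

- RMA background correction and probe-set summarization are out of scope;
  input matrices are assumed log2-summarized.
- The interaction edge list is consumed, never predicted; module detection
  is plain connected components, with no overlap or density criterion.
- The motif stage scans user-supplied consensus strings; de-novo discovery
  and PWM scoring are out of scope.
- Synthetic recovery rates (e.g. 96% recall at effect size 2) describe the
  generator's conditions and should not be read as expected performance on
  real arrays, where effects are smaller and noise is structured.
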