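# saltgenes

Trait-gene discovery from two-condition expression data, built around an
**improved volcano plot**: genes are selected not by fold change but by the
combination of a Welch t-test p-value and a bootstrap-stability score
(*MergeValue*) from linear SVM-RFE, then validated against quantitative
trait locus (QTL) intervals, predicted protein-interaction modules,
promoter-motif enrichment and co-expression. The package targets the
salt-tolerance setting in rice (*Oryza sativa*) — a small-sample
(3 genotypes × 3 replicates × 2 conditions), high-dimensional (tens of
thousands of probes) microarray design — but every stage is generic.

## The method

For probe *g* among *G* probes, class-stratified bootstrap resamples
*b = 1..B* of the samples are each ranked by linear SVM-RFE (recursive
feature elimination: train a soft-margin linear SVM on surviving features,
drop the lowest squared-weight 10%, repeat; rank 1 = eliminated last), and

```
MergeValue_g = (1/B) Σ_b (G − r_gb) / (G − 1)   ∈ [0, 1]
```

Genes with `p ≤ 0.05` (Welch t, two-sided) **and** `MergeValue ≥ 0.5` are
selected. Selections are validated with the **Microarray-QTL test**: with
*N* valid genes, *m* covered by QTL intervals, *n* selected and *k* selected-and-covered,
the p-value is the hypergeometric upper tail `P(K ≥ k)`,
optionally after extending each interval by one interval length per side
(3L total, clipped at chromosome ends) to tolerate QTL mapping error.
Selected genes plus a predicted-interaction edge list give a network whose
connected components (after merging `.1/.2/...` isoform suffixes to locus
level) are the modules; modules are corroborated by promoter-motif
chi-square enrichment (IUPAC consensus scan, 1,000-bp promoters) and by the
within-module vs random-set mean Pearson correlation contrast.

A seeded synthetic-data module generates expression matrices, genomes with
planted QTLs, isoform-suffixed interaction networks and motif-planted
promoter sets with known ground truth, so the full workflow runs and is
tested without any external downloads.

## Worked example

Run the numbered analysis steps (each is a thin driver over the library;
all write under `results/analysis/`):

```
python analysis/01_simulate_inputs.py --seed 1
python analysis/02_preprocess.py
python analysis/03_select_genes.py --seed 1
python analysis/04_qtl_enrichment.py
python analysis/05_network_modules.py --seed 1
python analysis/06_motif_enrichment.py
python analysis/07_coexpression.py --seed 1
```

Printed output (seed 1):

```
expression: 2000 probes x 18 samples (100 informative planted)
187 of 2000 probes selected at p <= 0.05, MergeValue >= 0.5; recall of planted informative probes 96.0%
curated salt-tolerance QTL table: 17 entries, 13 unique intervals
original intervals: 55/187 selected genes hit (29.41%), hypergeometric p = 2.49e-23
extended intervals: 69/187 selected genes hit (36.9%), hypergeometric p = 1.44e-10
246 raw isoform nodes -> 187 merged loci, 1309 edges
largest module: 115 nodes / 808 edges, hub LOC_SIMg00026 with degree 23, 29 QTL hits (39 extended)
TCTCTCTCT: present in 47/50 target vs 8/50 background promoters
chi-square = 61.45, p = 4.53e-15
largest module (115 genes): mean within-module r = 0.064 vs -0.008 against 1000 random size-matched sets (empirical p = 0.000999)
```

Reading this: 96 of the 100 probes that truly carry a 2-SD condition effect
pass both thresholds; the selected set over-occupies QTL territory far
beyond chance (upper-tail hypergeometric p ≈ 1e-23 for the original
intervals); the CT-rich consensus TCTCTCTCT is strongly enriched in the
target promoters; and the largest interaction module is more co-expressed
than random gene sets. The same workflow is available as one call
(`saltgenes run --seed 1 --out-dir out/`) or stage-by-stage through the
`saltgenes` CLI (`simulate`, `select`, `qtl-test`, `motif`, `coexpr`).

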