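#!/usr/bin/env python
"""Generate the synthetic study inputs every later step consumes.

Emulates the motivating design at desk scale: 2,000 probes x 18 samples
(3 genotypes x 3 replicates x control/salt), 100 probes carrying a
2-standard-deviation condition effect, a 4-chromosome genome with 8 QTL
intervals hosting half of the informative genes, and target/background
promoter sets with a CT-rich motif planted at 0.9 vs 0.2 presence.
"""

import argparse
from pathlib import Path

from saltgenes import simulate as sim

parser = argparse.ArgumentParser(description=__doc__)
parser.add_argument("--seed", type=int, default=1)
parser.add_argument("--out-dir", type=Path, default=Path("results/analysis/inputs"))
args = parser.parse_args()

out = args.out_dir
out.mkdir(parents=True, exist_ok=True)

expr_cfg = sim.ExprSimConfig(seed=args.seed)
matrix, truth = sim.simulate_expression(expr_cfg)
matrix.to_tsv(out / "expression.tsv", out / "labels.tsv")
truth.to_csv(out / "truth_informative.tsv", sep="\t")

genome_cfg = sim.GenomeSimConfig(n_genes=expr_cfg.n_probes, seed=args.seed + 1)
genes, qtls = sim.simulate_genome_qtls(
    genome_cfg, informative_ids=list(truth.index[truth["informative"]])
)
sim.write_gene_table(genes, out / "genes.tsv")
sim.write_qtl_table(qtls, out / "qtls.tsv")

prom_cfg = sim.PromoterSimConfig(seed=args.seed + 4)
target, background, prom_truth = sim.simulate_promoters(prom_cfg)
sim.write_fasta(target, out / "promoters_target.fasta")
sim.write_fasta(background, out / "promoters_background.fasta")
prom_truth.to_csv(out / "truth_promoters.tsv", sep="\t")

print(f"expression: {matrix.n_probes} probes x {matrix.n_samples} samples "
      f"({int(truth['informative'].sum())} informative planted)")
print(f"genome: {len(genes)} genes on {genome_cfg.n_chromosomes} chromosomes, "
      f"{len(qtls)} QTL intervals")
print(f"promoters: {len(target)} target / {len(background)} background "
      f"({prom_cfg.promoter_length} bp)")
print(f"inputs written to {out}")
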