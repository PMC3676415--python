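#!/usr/bin/env python
"""Validate the selected genes against QTL intervals (Microarray-QTL test).

Dedupes the interval table, extends each interval by one length per side,
maps genes by any-overlap, and tests whether the selected set over-occupies
(extended) QTL territory with the upper-tail hypergeometric test. Also
reports the dedupe census of the curated rice salt-tolerance QTL table
shipped with the package (17 entries, 13 unique).
"""

import argparse
from pathlib import Path

import pandas as pd

from saltgenes.pipeline import _enrichment_row
from saltgenes.qtl import dedupe_qtls, extend_interval, load_salt_qtls, read_qtl_table
from saltgenes.simulate import GenomeSimConfig, read_gene_table

parser = argparse.ArgumentParser(description=__doc__)
parser.add_argument("--seed", type=int, default=1)  # accepted so every step takes the same flags
parser.add_argument("--in-dir", type=Path, default=Path("results/analysis"))
parser.add_argument("--out-dir", type=Path, default=Path("results/analysis"))
args = parser.parse_args()

curated = load_salt_qtls()
print(f"curated salt-tolerance QTL table: {len(curated)} entries, "
      f"{len(dedupe_qtls(curated))} unique intervals")

inputs = args.in_dir / "inputs"
genes = read_gene_table(inputs / "genes.tsv")
chrom_length = GenomeSimConfig().chrom_length
qtls = [extend_interval(q, chrom_length) for q in dedupe_qtls(read_qtl_table(inputs / "qtls.tsv"))]
selected = set(pd.read_csv(args.in_dir / "selected_probes.txt", header=None)[0])
all_ids = list(genes["gene_id"].astype(str))

rows = [_enrichment_row(mode, genes, qtls, selected, all_ids) for mode in ("original", "extended")]
report = pd.DataFrame(rows)
args.out_dir.mkdir(parents=True, exist_ok=True)
report.to_csv(args.out_dir / "qtl_enrichment.tsv", sep="\t", index=False)

for row in rows:
    print(f"{row['mode']:>8} intervals: {row['k']}/{row['n']} selected genes hit "
          f"({row['pct_hits']}%), hypergeometric p = {row['p_value']:.3g}")
print(f"report -> {args.out_dir / 'qtl_enrichment.tsv'}")
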