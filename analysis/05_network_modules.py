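#!/usr/bin/env python
"""Build the selected-gene interaction network and identify its modules.

The selected genes become network nodes; a predicted-interaction edge list
(simulated here, with isoform-suffixed identifiers) supplies the edges.
Isoforms are merged to locus level, modules are the connected components
with >= 2 nodes, and each module is annotated with its (extended) QTL hits
and top hub degrees.
"""

import argparse
from pathlib import Path

import pandas as pd

from saltgenes.network import annotate_modules, find_modules, hub_degrees, induce_subnetwork, merge_isoforms
from saltgenes.qtl import dedupe_qtls, extend_interval, map_genes_to_intervals, read_qtl_table
from saltgenes.simulate import (
    GenomeSimConfig,
    NetworkSimConfig,
    read_gene_table,
    simulate_network,
    write_edge_list,
)

parser = argparse.ArgumentParser(description=__doc__)
parser.add_argument("--seed", type=int, default=1)
parser.add_argument("--in-dir", type=Path, default=Path("results/analysis"))
parser.add_argument("--out-dir", type=Path, default=Path("results/analysis"))
args = parser.parse_args()

selected = sorted(pd.read_csv(args.in_dir / "selected_probes.txt", header=None)[0])
net_cfg = NetworkSimConfig(n_nodes=len(selected), n_modules=min(8, len(selected)), seed=args.seed + 2)
edges, _ = simulate_network(net_cfg)
write_edge_list(edges, args.out_dir / "network_edges.tsv")

raw_nodes = {n for e in edges for n in e}
graph = merge_isoforms(edges)
locus_of = dict(zip(selected, sorted(graph.nodes)))
pd.DataFrame(locus_of.items(), columns=["probe_id", "locus"]).to_csv(
    args.out_dir / "locus_map.tsv", sep="\t", index=False
)
sub = induce_subnetwork(graph, set(locus_of.values()))
modules, singletons = find_modules(sub)
print(f"{len(raw_nodes)} raw isoform nodes -> {graph.number_of_nodes()} merged loci, "
      f"{graph.number_of_edges()} edges")
print(f"{len(modules)} modules (>= 2 nodes) and {len(singletons)} singletons")

inputs = args.in_dir / "inputs"
genes = read_gene_table(inputs / "genes.tsv")
qtls = [extend_interval(q, GenomeSimConfig().chrom_length)
        for q in dedupe_qtls(read_qtl_table(inputs / "qtls.tsv"))]
orig = map_genes_to_intervals(genes, qtls, mode="original")
ext = map_genes_to_intervals(genes, qtls, mode="extended")
orig_loci = {locus_of[g] for g in orig if g in locus_of}
ext_loci = {locus_of[g] for g in ext if g in locus_of}
modules = annotate_modules(modules, orig_loci, ext_loci)

rows = []
for i, m in enumerate(modules, start=1):
    hubs = hub_degrees(sub, m)
    rows.append({
        "module": i, "n_nodes": m.n_nodes, "n_edges": m.n_edges,
        "n_qtl_hits": len(m.qtl_hits), "n_extended_hits": len(m.extended_hits),
        "hub": hubs[0][0], "hub_degree": hubs[0][1],
        "members": ",".join(m.members),
    })
report = pd.DataFrame(rows)
report.to_csv(args.out_dir / "modules.tsv", sep="\t", index=False)

top = report.iloc[0]
print(f"largest module: {top['n_nodes']} nodes / {top['n_edges']} edges, "
      f"hub {top['hub']} with degree {top['hub_degree']}, "
      f"{top['n_qtl_hits']} QTL hits ({top['n_extended_hits']} extended)")
print(f"module table -> {args.out_dir / 'modules.tsv'}")
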