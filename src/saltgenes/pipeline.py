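"""End-to-end orchestration: simulate -> preprocess -> select -> validate.

`run_pipeline` wires every stage together from a single config and a global
seed, writing one report file per stage plus a JSON manifest. With no input
paths it runs entirely on the synthetic generators, which is the default and
the tested path; file-based inputs use the same TSV/FASTA dialects the
generators write. Outputs contain no timestamps so a rerun with the same
config is byte-identical.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from saltgenes import __version__
from saltgenes.coexpr import correlation_contrast
from saltgenes.motifs import MotifConsensus, chi_square_presence, presence_table, scan_motif
from saltgenes.network import annotate_modules, find_modules, induce_subnetwork, merge_isoforms
from saltgenes.preprocess import filter_control_probes, quantile_normalize
from saltgenes.qtl import (
    EnrichmentCounts,
    dedupe_qtls,
    extend_interval,
    hit_percentage,
    map_genes_to_intervals,
    microarray_qtl_test,
)
from saltgenes.selection import (
    RfeConfig,
    SelectionThresholds,
    improved_volcano_select,
    score_genes,
)
from saltgenes.simulate import (
    ExprSimConfig,
    GenomeSimConfig,
    NetworkSimConfig,
    PromoterSimConfig,
    simulate_expression,
    simulate_genome_qtls,
    simulate_network,
    simulate_promoters,
)

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_pipeline"]


@dataclass
class PipelineConfig:
    """One config to drive the whole workflow on synthetic inputs.

    The global ``seed`` is offset per stage so stages draw independent
    streams but the whole run is reproducible. ``qtl_mode`` selects which
    interval bounds the enrichment report includes (original/extended/both).
    """

    out_dir: str | Path = "pipeline_out"
    seed: int = 0
    expr: ExprSimConfig | None = None
    genome: GenomeSimConfig | None = None
    network: NetworkSimConfig | None = None
    promoters: PromoterSimConfig | None = None
    thresholds: SelectionThresholds = field(default_factory=SelectionThresholds)
    rfe: RfeConfig | None = None
    qtl_mode: str = "both"
    n_random_coexpr: int = 200

    def __post_init__(self) -> None:
        if self.qtl_mode not in ("original", "extended", "both"):
            raise ValueError("qtl_mode must be original, extended or both")
        # stage seeds derive deterministically from the global seed
        if self.expr is None:
            self.expr = ExprSimConfig(seed=self.seed)
        if self.genome is None:
            self.genome = GenomeSimConfig(n_genes=self.expr.n_probes, seed=self.seed + 1)
        # network defaults are resolved inside run_pipeline: the interaction
        # network is built over the selected genes, whose count is only known
        # after the selection stage
        if self.rfe is None:
            # desk-scale bootstrap count; the library default is 50
            self.rfe = RfeConfig(n_bootstraps=20, seed=self.seed + 3)


def _enrichment_row(mode: str, genes, intervals, selected, all_ids) -> dict:
    hits_all = map_genes_to_intervals(genes, intervals, mode=mode)
    hits_sel = {g for g in selected if g in hits_all}
    counts = EnrichmentCounts(
        N=len(all_ids), m=len(hits_all & set(all_ids)), n=len(selected), k=len(hits_sel)
    )
    return {
        "mode": mode,
        "N": counts.N,
        "m": counts.m,
        "n": counts.n,
        "k": counts.k,
        "pct_hits": hit_percentage(counts.k, counts.n) if counts.n else 0.0,
        "p_value": microarray_qtl_test(counts),
    }


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Run every stage and write stage reports under ``cfg.out_dir``.

    Returns a summary dict (also written as ``manifest.json``). Raises with
    the failing stage's name; reports written before the failure remain.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    summary: dict = {
        "version": __version__,
        "seed": cfg.seed,
        "thresholds": {"p_max": cfg.thresholds.p_max, "merge_min": cfg.thresholds.merge_min},
    }
    stage = "simulate"
    try:
        t0 = time.perf_counter()
        matrix, truth = simulate_expression(cfg.expr)
        genes, qtls_raw = simulate_genome_qtls(
            cfg.genome, informative_ids=list(truth.index[truth["informative"]])
        )
        logger.info("stage %s done in %.1fs", stage, time.perf_counter() - t0)

        stage = "preprocess"
        t0 = time.perf_counter()
        # synthetic matrices carry no control probes: the filter is an identity
        matrix = filter_control_probes(matrix, control_ids=set())
        matrix = quantile_normalize(matrix)
        logger.info("stage %s done in %.1fs", stage, time.perf_counter() - t0)

        stage = "select"
        t0 = time.perf_counter()
        scores = score_genes(matrix, cfg.rfe)
        qtls = dedupe_qtls(qtls_raw)
        qtls = [extend_interval(q, cfg.genome.chrom_length) for q in qtls]
        qtl_gene_hits = map_genes_to_intervals(genes, qtls, mode="original")
        selected, volcano = improved_volcano_select(scores, cfg.thresholds, qtl_hits=qtl_gene_hits)
        scores.join(volcano[["selected", "stratum", "neg_log10_p"]]).rename_axis(
            "probe_id"
        ).to_csv(out / "selection.tsv", sep="\t")
        n_informative_selected = int(truth.loc[sorted(selected), "informative"].sum())
        summary["selection"] = {
            "n_selected": len(selected),
            "n_informative": int(truth["informative"].sum()),
            "n_informative_selected": n_informative_selected,
            "recall": n_informative_selected / max(1, int(truth["informative"].sum())),
        }
        logger.info("stage %s done in %.1fs", stage, time.perf_counter() - t0)

        stage = "qtl-test"
        t0 = time.perf_counter()
        modes = ["original", "extended"] if cfg.qtl_mode == "both" else [cfg.qtl_mode]
        all_ids = list(matrix.values.index)
        enr = pd.DataFrame(
            [_enrichment_row(m, genes, qtls, selected, all_ids) for m in modes]
        )
        enr.to_csv(out / "qtl_enrichment.tsv", sep="\t", index=False)
        summary["qtl_enrichment"] = enr.to_dict(orient="records")
        logger.info("stage %s done in %.1fs", stage, time.perf_counter() - t0)

        stage = "network"
        t0 = time.perf_counter()
        # the interaction network is built over the selected genes (the
        # selected set are the nodes; a predicted-interaction dump supplies
        # the edges — simulated here, one network node per selected probe)
        n_net_nodes = max(len(selected), 2)
        net_cfg = cfg.network or NetworkSimConfig(
            n_nodes=n_net_nodes, n_modules=min(8, n_net_nodes), seed=cfg.seed + 2
        )
        edges, _net_truth = simulate_network(net_cfg)
        graph = merge_isoforms(edges)
        # synthetic network loci pair with selected probes by sorted order
        locus_of = dict(zip(sorted(selected), sorted(graph.nodes)))
        selected_loci = set(locus_of.values())
        sub = induce_subnetwork(graph, selected_loci)
        modules, singletons = find_modules(sub)
        orig_hits = {locus_of[g] for g in qtl_gene_hits if g in locus_of}
        ext_hits_probes = map_genes_to_intervals(genes, qtls, mode="extended")
        ext_hits = {locus_of[g] for g in ext_hits_probes if g in locus_of}
        modules = annotate_modules(modules, orig_hits, ext_hits)
        mod_table = pd.DataFrame(
            [
                {
                    "module": i + 1,
                    "n_nodes": m.n_nodes,
                    "n_edges": m.n_edges,
                    "n_qtl_hits": len(m.qtl_hits),
                    "n_extended_hits": len(m.extended_hits),
                    "has_extended_hit": m.has_extended_hit,
                    "members": ",".join(m.members),
                }
                for i, m in enumerate(modules)
            ]
        )
        mod_table.to_csv(out / "modules.tsv", sep="\t", index=False)
        summary["network"] = {
            "n_nodes": sub.number_of_nodes(),
            "n_edges": sub.number_of_edges(),
            "n_modules": len(modules),
            "n_singletons": len(singletons),
            "largest_module_nodes": modules[0].n_nodes if modules else 0,
            "largest_module_edges": modules[0].n_edges if modules else 0,
        }
        logger.info("stage %s done in %.1fs", stage, time.perf_counter() - t0)

        stage = "motif"
        t0 = time.perf_counter()
        prom_cfg = cfg.promoters or PromoterSimConfig(
            n_target=max(2, modules[0].n_nodes if modules else 2), seed=cfg.seed + 4
        )
        target, background, _ = simulate_promoters(prom_cfg)
        motif = MotifConsensus("planted", prom_cfg.planted_motif)
        tab = presence_table(scan_motif(target, motif), scan_motif(background, motif))
        chi2, p, low_expected = chi_square_presence(tab)
        motif_report = {
            "motif": motif.iupac,
            "target_present": tab.target_present,
            "target_absent": tab.target_absent,
            "background_present": tab.background_present,
            "background_absent": tab.background_absent,
            "chi2": chi2,
            "p_value": p,
            "low_expected_warning": low_expected,
        }
        pd.DataFrame([motif_report]).to_csv(out / "motif_enrichment.tsv", sep="\t", index=False)
        summary["motif"] = motif_report
        logger.info("stage %s done in %.1fs", stage, time.perf_counter() - t0)

        stage = "coexpr"
        t0 = time.perf_counter()
        if modules:
            probe_of = {v: k for k, v in locus_of.items()}
            module_probes = [probe_of[l] for l in modules[0].members if l in probe_of]
            res = correlation_contrast(
                matrix, module_probes, n_random=cfg.n_random_coexpr, seed=cfg.seed + 5
            )
            coexpr_report = {
                "within_mean": res.within_mean,
                "random_mean": res.random_mean,
                "n_random_draws": res.n_random_draws,
                "empirical_p": res.empirical_p,
            }
        else:
            coexpr_report = {"within_mean": None, "random_mean": None,
                             "n_random_draws": 0, "empirical_p": None}
        pd.DataFrame([coexpr_report]).to_csv(out / "coexpression.tsv", sep="\t", index=False)
        summary["coexpression"] = coexpr_report
        logger.info("stage %s done in %.1fs", stage, time.perf_counter() - t0)
    except Exception as exc:  # noqa: BLE001 - annotate with the failing stage
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    with open(out / "manifest.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
    return summary
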