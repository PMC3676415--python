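"""Seeded synthetic inputs with the statistical structure the pipeline assumes.

Four generators emulate the study's data sources at desk scale:

* an expression matrix from a two-condition design (default 3 genotypes x 3
  replicates x 2 conditions = 18 samples; 2,000 probes of which 100 carry a
  condition effect — a 1/30-scale stand-in for a ~57k-probe array),
* a genome with gene coordinates and planted QTL intervals,
* a protein-interaction edge list with planted dense modules and
  isoform-suffixed node names,
* promoter FASTA sets with a motif planted at given presence rates.

Every generator is a pure function of its config (including the seed):
identical configs give identical outputs. Expression noise is Gaussian on
the log2 scale with a small additive per-genotype offset (0.2 x noise_sd)
so pooling genotypes into one class is meaningfully exercised; the true
noise model of the motivating array is unknown and these choices are
documented stand-ins.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from saltgenes.motifs import IUPAC_SETS, MotifConsensus
from saltgenes.preprocess import ExpressionMatrix
from saltgenes.qtl import QtlInterval

__all__ = [
    "ExprSimConfig",
    "GenomeSimConfig",
    "NetworkSimConfig",
    "PromoterSimConfig",
    "simulate_expression",
    "simulate_genome_qtls",
    "simulate_network",
    "simulate_promoters",
    "write_gene_table",
    "write_qtl_table",
    "write_edge_list",
    "write_fasta",
]

GENOTYPE_EFFECT_SCALE = 0.2  # per-genotype offset, in units of noise_sd


@dataclass(frozen=True)
class ExprSimConfig:
    """Two-condition expression design (control +1 vs stressed -1)."""

    n_probes: int = 2000
    n_genotypes: int = 3
    n_reps_per_condition: int = 3
    n_informative: int = 100
    effect_size: float = 2.0  # class mean shift in units of noise_sd
    noise_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_probes < 1 or self.n_genotypes < 1 or self.n_reps_per_condition < 1:
            raise ValueError("counts must be positive")
        if self.n_informative > self.n_probes or self.n_informative < 0:
            raise ValueError("n_informative must lie in [0, n_probes]")
        if self.effect_size < 0:
            raise ValueError("effect_size must be >= 0")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")

    @property
    def n_samples(self) -> int:
        return self.n_genotypes * self.n_reps_per_condition * 2


@dataclass(frozen=True)
class GenomeSimConfig:
    """Synthetic genome layout with planted QTL intervals."""

    n_chromosomes: int = 4
    chrom_length: int = 2_000_000
    n_genes: int = 2000
    n_qtls: int = 8
    qtl_length_min: int = 20_000
    qtl_length_max: int = 120_000
    planted_overlap_fraction: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.qtl_length_max > self.chrom_length:
            raise ValueError("QTL cannot fit on a chromosome")
        if not 0 <= self.planted_overlap_fraction <= 1:
            raise ValueError("planted_overlap_fraction must be a fraction")
        if self.qtl_length_min > self.qtl_length_max or self.qtl_length_min < 1:
            raise ValueError("invalid QTL length range")


@dataclass(frozen=True)
class NetworkSimConfig:
    """Planted-module interaction network with isoform-suffixed node names."""

    n_nodes: int = 200
    n_modules: int = 8
    within_module_edge_prob: float = 0.6
    background_edge_prob: float = 0.0002
    isoform_rate: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        for p in (self.within_module_edge_prob, self.background_edge_prob, self.isoform_rate):
            if not 0 <= p <= 1:
                raise ValueError("probabilities must lie in [0, 1]")
        if self.n_modules < 1 or self.n_nodes < self.n_modules:
            raise ValueError("need at least one node per module")


@dataclass(frozen=True)
class PromoterSimConfig:
    """Target/background promoter sets with a planted IUPAC motif."""

    n_target: int = 50
    n_background: int = 50
    promoter_length: int = 1000
    planted_motif: str = "TCTCTCTCT"
    target_presence_rate: float = 0.9
    background_presence_rate: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        MotifConsensus("planted", self.planted_motif)  # validates IUPAC
        if len(self.planted_motif) > self.promoter_length:
            raise ValueError("motif longer than promoter")
        for r in (self.target_presence_rate, self.background_presence_rate):
            if not 0 <= r <= 1:
                raise ValueError("presence rates must lie in [0, 1]")


def simulate_expression(cfg: ExprSimConfig) -> tuple[ExpressionMatrix, pd.DataFrame]:
    """Expression matrix plus a truth table flagging informative probes.

    Informative probes shift their stressed-class mean by
    ``effect_size x noise_sd``; a per-(genotype, probe) Gaussian offset of
    ``0.2 x noise_sd`` models genotype heterogeneity. Baselines are uniform
    on [4, 12] log2 units.
    """
    rng = np.random.default_rng(cfg.seed)
    probe_ids = [f"PROBE_{i:05d}" for i in range(cfg.n_probes)]
    sample_ids, labels, genotype_of = [], {}, []
    for g in range(cfg.n_genotypes):
        for condition, cls in (("C", 1), ("S", -1)):
            for r in range(cfg.n_reps_per_condition):
                sid = f"G{g + 1}_{condition}{r + 1}"
                sample_ids.append(sid)
                labels[sid] = cls
                genotype_of.append(g)
    informative = np.zeros(cfg.n_probes, dtype=bool)
    informative[rng.choice(cfg.n_probes, size=cfg.n_informative, replace=False)] = True
    baseline = rng.uniform(4.0, 12.0, size=cfg.n_probes)
    genotype_offsets = rng.normal(
        0.0, GENOTYPE_EFFECT_SCALE * cfg.noise_sd, size=(cfg.n_probes, cfg.n_genotypes)
    )
    cls_vec = np.array([labels[s] for s in sample_ids])
    X = baseline[:, None] + rng.normal(0.0, cfg.noise_sd, size=(cfg.n_probes, len(sample_ids)))
    X += genotype_offsets[:, genotype_of]
    # stressed samples (class -1) of informative probes get the full shift
    shift = cfg.effect_size * cfg.noise_sd
    X[np.ix_(informative, cls_vec == -1)] += shift
    matrix = ExpressionMatrix(
        values=pd.DataFrame(X, index=probe_ids, columns=sample_ids), labels=labels
    )
    truth = pd.DataFrame({"probe_id": probe_ids, "informative": informative}).set_index(
        "probe_id"
    )
    return matrix, truth


def simulate_genome_qtls(
    cfg: GenomeSimConfig, informative_ids: list[str] | None = None
) -> tuple[pd.DataFrame, list[QtlInterval]]:
    """Gene coordinate table (1-based inclusive) plus QTL interval list.

    Genes are 1 kb bodies placed uniformly; QTL intervals are placed first and
    ``planted_overlap_fraction`` of the informative genes are then relocated
    inside a random QTL so downstream enrichment has signal by construction.
    ``informative_ids`` defaults to none; ids follow ``PROBE_#####`` so the
    probe-to-gene map is the identity.
    """
    rng = np.random.default_rng(cfg.seed)
    gene_ids = [f"PROBE_{i:05d}" for i in range(cfg.n_genes)]
    if informative_ids is not None:
        unknown = set(informative_ids) - set(gene_ids)
        if unknown:
            raise ValueError(f"informative ids outside the generated gene set: {sorted(unknown)[:5]}")
    qtls: list[QtlInterval] = []
    for q in range(cfg.n_qtls):
        chrom = str(rng.integers(1, cfg.n_chromosomes + 1))
        L = int(rng.integers(cfg.qtl_length_min, cfg.qtl_length_max + 1))
        start = int(rng.integers(1, cfg.chrom_length - L + 2))
        qtls.append(QtlInterval(f"SIMQTL{q + 1:03d}", chrom, start, start + L - 1))

    gene_len = 1000
    chroms = rng.integers(1, cfg.n_chromosomes + 1, size=cfg.n_genes)
    starts = rng.integers(1, cfg.chrom_length - gene_len + 1, size=cfg.n_genes)
    genes = pd.DataFrame(
        {
            "chrom": chroms.astype(str),
            "start": starts,
            "end": starts + gene_len - 1,
            "gene_id": gene_ids,
            "score": 0,
            "strand": rng.choice(["+", "-"], size=cfg.n_genes),
        }
    )
    if informative_ids and qtls and cfg.planted_overlap_fraction > 0:
        informative_ids = sorted(informative_ids)
        n_plant = int(round(cfg.planted_overlap_fraction * len(informative_ids)))
        planted = rng.choice(len(informative_ids), size=n_plant, replace=False)
        gene_pos = {gid: i for i, gid in enumerate(gene_ids)}
        for j in planted:
            gid = informative_ids[j]
            q = qtls[int(rng.integers(len(qtls)))]
            # place the gene body fully inside the interval (QTLs >> gene length)
            hi = max(q.start, q.end - gene_len + 1)
            s = int(rng.integers(q.start, hi + 1))
            i = gene_pos[gid]
            genes.loc[i, ["chrom", "start", "end"]] = (q.chrom, s, s + gene_len - 1)
    return genes, qtls


def _partition_nodes(n_nodes: int, n_modules: int, rng: np.random.Generator) -> np.ndarray:
    """Random module assignment with every module nonempty."""
    assign = rng.integers(0, n_modules, size=n_nodes)
    assign[:n_modules] = np.arange(n_modules)  # guarantee nonempty
    return assign


def simulate_network(cfg: NetworkSimConfig) -> tuple[list[tuple[str, str]], pd.DataFrame]:
    """Edge list with isoform-suffixed names plus the truth module table.

    Within-module pairs connect with ``within_module_edge_prob``; cross-module
    pairs with ``background_edge_prob``. A fraction ``isoform_rate`` of loci
    is emitted as two suffixed isoforms (``LOCUS.1``/``LOCUS.2``) that share
    every edge of the locus, so isoform merging reconstructs the truth graph.
    """
    rng = np.random.default_rng(cfg.seed)
    loci = [f"LOC_SIMg{i:05d}" for i in range(cfg.n_nodes)]
    assign = _partition_nodes(cfg.n_nodes, cfg.n_modules, rng)
    edges_locus: list[tuple[int, int]] = []
    for i in range(cfg.n_nodes):
        for j in range(i + 1, cfg.n_nodes):
            p = cfg.within_module_edge_prob if assign[i] == assign[j] else cfg.background_edge_prob
            if rng.random() < p:
                edges_locus.append((i, j))
    split = rng.random(cfg.n_nodes) < cfg.isoform_rate
    def emits(i: int) -> list[str]:
        return [f"{loci[i]}.1", f"{loci[i]}.2"] if split[i] else [loci[i]]
    edges: list[tuple[str, str]] = []
    for i, j in edges_locus:
        for a in emits(i):
            for b in emits(j):
                edges.append((a, b))
    truth = pd.DataFrame({"locus": loci, "module": assign, "is_split": split}).set_index("locus")
    return edges, truth


def _realize_motif(iupac: str, rng: np.random.Generator) -> str:
    return "".join(rng.choice(sorted(IUPAC_SETS[c])) for c in iupac)


def _random_seq(length: int, rng: np.random.Generator) -> np.ndarray:
    return rng.choice(np.array(list("ACGT")), size=length)


def simulate_promoters(
    cfg: PromoterSimConfig,
) -> tuple[dict[str, str], dict[str, str], pd.DataFrame]:
    """Target and background promoter sets plus per-sequence truth flags.

    The planted motif (one concrete realization per insertion) is written at
    a uniform random offset into the stated fraction of each set; all other
    bases are i.i.d. uniform A/C/G/T.
    """
    rng = np.random.default_rng(cfg.seed)
    truth_rows = []

    def build(prefix: str, n: int, rate: float) -> dict[str, str]:
        out = {}
        for i in range(n):
            name = f"{prefix}_{i:04d}"
            seq = _random_seq(cfg.promoter_length, rng)
            planted = bool(rng.random() < rate)
            if planted:
                motif = _realize_motif(cfg.planted_motif, rng)
                offset = int(rng.integers(0, cfg.promoter_length - len(motif) + 1))
                seq[offset : offset + len(motif)] = list(motif)
            out[name] = "".join(seq)
            truth_rows.append({"seq_id": name, "set": prefix, "planted": planted})
        return out

    target = build("target", cfg.n_target, cfg.target_presence_rate)
    background = build("background", cfg.n_background, cfg.background_presence_rate)
    truth = pd.DataFrame(truth_rows).set_index("seq_id")
    return target, background, truth


# --- plain-text writers (the TSV/FASTA dialects shared across the package) --

def write_gene_table(genes: pd.DataFrame, path: str | Path) -> None:
    """6-column BED-like TSV, declared 1-based inclusive."""
    with open(path, "w") as fh:
        fh.write("#coordinates=1-based-inclusive\n")
        genes[["chrom", "start", "end", "gene_id", "score", "strand"]].to_csv(
            fh, sep="\t", index=False
        )


def read_gene_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", dtype={"chrom": str})


def write_qtl_table(qtls: list[QtlInterval], path: str | Path) -> None:
    pd.DataFrame(
        [{"qtl_id": q.qtl_id, "chrom": q.chrom, "start": q.start, "end": q.end} for q in qtls]
    ).to_csv(path, sep="\t", index=False)


def write_edge_list(edges: list[tuple[str, str]], path: str | Path) -> None:
    pd.DataFrame(edges, columns=["node_a", "node_b"]).to_csv(path, sep="\t", index=False)


def read_edge_list(path: str | Path) -> list[tuple[str, str]]:
    df = pd.read_csv(path, sep="\t")
    return list(df.itertuples(index=False, name=None))


def write_fasta(sequences: dict[str, str], path: str | Path) -> None:
    from Bio.Seq import Seq
    from Bio.SeqIO import write as seqio_write
    from Bio.SeqRecord import SeqRecord

    records = [SeqRecord(Seq(s), id=name, description="") for name, s in sequences.items()]
    seqio_write(records, str(path), "fasta")


def read_fasta(path: str | Path) -> dict[str, str]:
    from Bio import SeqIO

    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}
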