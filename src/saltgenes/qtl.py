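"""QTL-interval handling and the Microarray-QTL hypergeometric test.

Selected genes are validated against quantitative trait locus (QTL)
intervals: a gene "hits" an interval when its body overlaps it by at least
one base. Significance of the overlap is the upper tail of a hypergeometric
distribution: with N valid genes on the array, m of them covered by QTL
intervals, and n chosen genes of which k are covered,

    p = P(K >= k),  K ~ Hypergeometric(N, m, n).

Intervals may also be extended by one interval length on each side (total
3L, clipped at chromosome ends) to tolerate QTL mapping error. The same
hypergeometric machinery doubles as a generic term-enrichment test with
Benjamini-Hochberg FDR control.

All interval and gene coordinates in this module are 1-based inclusive (the
convention of the source QTL tables); conversion to half-open happens in one
place (`_to_half_open`).
"""

from __future__ import annotations

import importlib.resources
import logging
from dataclasses import dataclass, replace

import pandas as pd
from intervaltree import IntervalTree
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

__all__ = [
    "QtlInterval",
    "EnrichmentCounts",
    "load_salt_qtls",
    "read_qtl_table",
    "dedupe_qtls",
    "extend_interval",
    "map_genes_to_intervals",
    "microarray_qtl_test",
    "hit_percentage",
    "term_enrichment",
]


@dataclass(frozen=True)
class QtlInterval:
    """Named 1-based inclusive genomic interval with optional extended bounds."""

    qtl_id: str
    chrom: str
    start: int
    end: int
    extended_start: int | None = None
    extended_end: int | None = None
    aliases: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"interval {self.qtl_id}: start {self.start} > end {self.end}")
        if self.start < 1:
            raise ValueError(f"interval {self.qtl_id}: 1-based start must be >= 1")

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    @property
    def key(self) -> tuple[str, int, int]:
        return (self.chrom, self.start, self.end)


@dataclass(frozen=True)
class EnrichmentCounts:
    """The (N, m, n, k) quadruple of the Microarray-QTL test."""

    N: int
    m: int
    n: int
    k: int

    def __post_init__(self) -> None:
        if not (0 <= self.m <= self.N and 0 <= self.n <= self.N):
            raise ValueError(f"m and n must lie in [0, N]: {self}")
        if not 0 <= self.k <= min(self.m, self.n):
            raise ValueError(f"k must lie in [0, min(m, n)]: {self}")


def read_qtl_table(path) -> list[QtlInterval]:
    """Read a QTL TSV (qtl_id, chrom, start, end), 1-based inclusive."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    out = []
    for row in df.itertuples(index=False):
        if row.start > row.end:
            raise ValueError(f"malformed interval in row {row.qtl_id}: start > end")
        out.append(QtlInterval(str(row.qtl_id), str(row.chrom), int(row.start), int(row.end)))
    return out


def load_salt_qtls() -> list[QtlInterval]:
    """The packaged rice salt-tolerance QTL table (17 Gramene entries)."""
    ref = importlib.resources.files("saltgenes.data").joinpath("gramene_salt_qtls.tsv")
    with importlib.resources.as_file(ref) as path:
        return read_qtl_table(path)


def dedupe_qtls(intervals: list[QtlInterval]) -> list[QtlInterval]:
    """Collapse intervals identical in (chrom, start, end); first id wins.

    Collapsed ids are recorded on the survivor's ``aliases``.
    """
    seen: dict[tuple[str, int, int], QtlInterval] = {}
    order: list[tuple[str, int, int]] = []
    for iv in intervals:
        if iv.key in seen:
            survivor = seen[iv.key]
            seen[iv.key] = replace(survivor, aliases=survivor.aliases + (iv.qtl_id,))
        else:
            seen[iv.key] = iv
            order.append(iv.key)
    return [seen[k] for k in order]


def extend_interval(q: QtlInterval, chrom_length: int) -> QtlInterval:
    """Flank the interval by one interval length per side, clipped to the chromosome."""
    if chrom_length < q.end:
        raise ValueError(
            f"chromosome length {chrom_length} shorter than interval end {q.end} ({q.qtl_id})"
        )
    L = q.length
    return replace(
        q,
        extended_start=max(1, q.start - L),
        extended_end=min(chrom_length, q.end + L),
    )


def _to_half_open(start_1based: int, end_1based_inclusive: int) -> tuple[int, int]:
    """Single conversion point: 1-based inclusive -> 0-based half-open."""
    return start_1based - 1, end_1based_inclusive


def map_genes_to_intervals(
    genes: pd.DataFrame,
    intervals: list[QtlInterval],
    mode: str = "original",
) -> set[str]:
    """Gene ids whose body overlaps any interval by >= 1 base (same chromosome).

    ``genes`` is a BED-like table with columns ``chrom, start, end, gene_id``
    (1-based inclusive). ``mode`` selects ``original`` or ``extended`` bounds;
    extended mode requires `extend_interval` to have been applied. Genes on
    chromosomes with no intervals simply miss; unknown columns are ignored.
    """
    if mode not in ("original", "extended"):
        raise ValueError("mode must be 'original' or 'extended'")
    trees: dict[str, IntervalTree] = {}
    for iv in intervals:
        if mode == "extended":
            if iv.extended_start is None or iv.extended_end is None:
                raise ValueError(f"interval {iv.qtl_id} has no extended bounds")
            s, e = _to_half_open(iv.extended_start, iv.extended_end)
        else:
            s, e = _to_half_open(iv.start, iv.end)
        trees.setdefault(str(iv.chrom), IntervalTree()).addi(s, e)
    hits: set[str] = set()
    for row in genes.itertuples(index=False):
        chrom = str(row.chrom)
        tree = trees.get(chrom)
        if tree is None:
            continue
        s, e = _to_half_open(int(row.start), int(row.end))
        if tree.overlap(s, e):
            hits.add(str(row.gene_id))
    return hits


def microarray_qtl_test(counts: EnrichmentCounts) -> float:
    """Upper-tail hypergeometric probability P(K >= k)."""
    return float(hypergeom.sf(counts.k - 1, counts.N, counts.m, counts.n))


def hit_percentage(k: int, n: int) -> float:
    """Percentage of chosen genes hitting intervals, rounded to 2 decimals."""
    if n <= 0:
        raise ValueError("n must be positive")
    return round(100.0 * k / n, 2)


def term_enrichment(
    selected: set[str],
    term_map: dict[str, set[str]],
    background: set[str],
) -> pd.DataFrame:
    """Hypergeometric term enrichment with Benjamini-Hochberg FDR.

    ``term_map`` maps term -> annotated gene set. Term sizes are counted
    within ``background``; ``selected`` must be a subset of ``background``.
    Returns a DataFrame indexed by term with columns
    ``n_selected, n_background, p_value, fdr`` sorted by p-value.
    """
    if not selected:
        raise ValueError("empty selected gene set")
    stray = selected - background
    if stray:
        raise ValueError(f"selected genes absent from background: {sorted(stray)[:5]}")
    rows = {}
    for term, members in term_map.items():
        members_bg = members & background
        counts = EnrichmentCounts(
            N=len(background),
            m=len(members_bg),
            n=len(selected),
            k=len(members_bg & selected),
        )
        rows[term] = {
            "n_selected": counts.k,
            "n_background": counts.m,
            "p_value": microarray_qtl_test(counts),
        }
    table = pd.DataFrame.from_dict(rows, orient="index")
    table["fdr"] = multipletests(table["p_value"].to_numpy(), method="fdr_bh")[1]
    return table.sort_values("p_value")
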