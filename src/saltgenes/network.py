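"""Interaction-network construction, isoform merging and module detection.

Protein identifiers carry splice-variant suffixes (``LOC_Os01g61610.2``);
isoforms of a locus are collapsed into one node, re-keying edges to locus
level, dropping self-loops that arise from isoform-isoform pairs and
collapsing parallel edges. A module is a connected component (with at least
two nodes) of the subnetwork induced by the selected loci; the hub of a
module is its highest-degree member.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field

import networkx as nx

logger = logging.getLogger(__name__)

__all__ = [
    "Module",
    "merge_isoforms",
    "locus_id",
    "induce_subnetwork",
    "find_modules",
    "annotate_modules",
    "hub_degrees",
]

_ISOFORM_SUFFIX = re.compile(r"\.\d+$")


def locus_id(identifier: str) -> str:
    """Strip a trailing ``.<integer>`` isoform suffix; other ids pass through."""
    return _ISOFORM_SUFFIX.sub("", identifier)


@dataclass
class Module:
    """A connected group of interacting loci with QTL-hit annotation."""

    members: list[str]
    n_edges: int
    qtl_hits: list[str] = field(default_factory=list)
    extended_hits: list[str] = field(default_factory=list)
    label: str | None = None

    @property
    def n_nodes(self) -> int:
        return len(self.members)

    @property
    def has_extended_hit(self) -> bool:
        return len(self.extended_hits) > 0

    @property
    def flank_only_hits(self) -> list[str]:
        """Hits in the extended region but outside the original interval."""
        original = set(self.qtl_hits)
        return [g for g in self.extended_hits if g not in original]


def merge_isoforms(edges: list[tuple[str, str]]) -> nx.Graph:
    """Collapse isoform-suffixed ids to loci and build the undirected graph.

    Isoform membership per merged node is stored in the ``isoforms`` node
    attribute. Self-loops (isoform pairs of one locus) are dropped.
    """
    graph = nx.Graph()
    for a, b in edges:
        if not a or not b:
            raise ValueError("empty node identifier in edge list")
        la, lb = locus_id(a), locus_id(b)
        for raw, locus in ((a, la), (b, lb)):
            if locus not in graph:
                graph.add_node(locus, isoforms=set())
            if raw != locus:
                graph.nodes[locus]["isoforms"].add(raw)
        if la == lb:
            continue
        graph.add_edge(la, lb)
    return graph


def induce_subnetwork(graph: nx.Graph, selected: set[str]) -> nx.Graph:
    """Subgraph on ``selected`` loci; isolated selected nodes are retained."""
    present = set(graph.nodes) & set(selected)
    if not present:
        logger.warning("no selected locus found in the interaction graph")
    return graph.subgraph(present).copy()


def find_modules(graph: nx.Graph) -> tuple[list[Module], list[str]]:
    """Connected components with >= 2 nodes, plus the singleton list.

    Modules are sorted by (node count desc, edge count desc, smallest member
    id); members are sorted lexicographically within a module.
    """
    modules: list[Module] = []
    singletons: list[str] = []
    for comp in nx.connected_components(graph):
        if len(comp) < 2:
            singletons.extend(comp)
            continue
        sub = graph.subgraph(comp)
        modules.append(Module(members=sorted(comp), n_edges=sub.number_of_edges()))
    modules.sort(key=lambda m: (-m.n_nodes, -m.n_edges, m.members[0]))
    return modules, sorted(singletons)


def annotate_modules(
    modules: list[Module],
    qtl_hit_loci: set[str],
    extended_hit_loci: set[str],
) -> list[Module]:
    """Attach per-module QTL-hit member lists and the >= 1-extended-hit flag.

    ``extended_hit_loci`` must contain ``qtl_hit_loci`` (extended intervals
    contain the originals). The flag is reported, not used to delete modules.
    """
    extended_hit_loci = set(extended_hit_loci) | set(qtl_hit_loci)
    all_members = set().union(*(m.members for m in modules)) if modules else set()
    if modules and qtl_hit_loci and not (all_members & extended_hit_loci):
        logger.warning("no overlap between module members and QTL hit sets; namespace mismatch?")
    for m in modules:
        m.qtl_hits = [g for g in m.members if g in qtl_hit_loci]
        m.extended_hits = [g for g in m.members if g in extended_hit_loci]
    return modules


def hub_degrees(graph: nx.Graph, module: Module) -> list[tuple[str, int]]:
    """(locus, degree) within the module's induced subgraph, degree descending.

    Ties break lexicographically on the locus id.
    """
    if not module.members:
        raise ValueError("empty module")
    sub = graph.subgraph(module.members)
    return sorted(sub.degree, key=lambda kv: (-kv[1], kv[0]))
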