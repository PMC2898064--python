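"""Merged FI network: construction, descriptive statistics, and the GO
cellular-component sharing check.

The network is an undirected :class:`networkx.Graph` whose edges carry the
FI annotations (provenance, direction, direction source, source labels).
When the same pair is reported by both a pathway extraction and the
classifier, the pathway report wins: its provenance and direction are
kept and the source labels are unioned.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Set, Tuple

import networkx as nx

from .pathway import Direction, FunctionalInteraction, merge_fi

__all__ = [
    "NetworkStats",
    "build_network",
    "network_fis",
    "merge_fi_network",
    "network_stats",
    "cc_sharing_rate",
    "map_to_gene_symbols",
    "largest_component",
]

logger = logging.getLogger(__name__)


def build_network(fis: Iterable[FunctionalInteraction]) -> nx.Graph:
    """Graph over an FI set; duplicate pairs are merged."""
    by_pair: Dict[Tuple[str, str], FunctionalInteraction] = {}
    for fi in sorted(fis, key=lambda f: (f.pair, f.provenance)):
        if fi.pair in by_pair:
            by_pair[fi.pair] = merge_fi(by_pair[fi.pair], fi)
        else:
            by_pair[fi.pair] = fi
    g = nx.Graph()
    for fi in by_pair.values():
        g.add_edge(
            fi.pair[0],
            fi.pair[1],
            provenance=fi.provenance,
            direction=fi.direction,
            direction_source=fi.direction_source,
            sources=set(fi.sources),
        )
    return g


def network_fis(g: nx.Graph) -> Set[FunctionalInteraction]:
    """Recover the FI set from an annotated network."""
    return {
        FunctionalInteraction(
            pair=(a, b) if a <= b else (b, a),
            provenance=d.get("provenance", "pathway"),
            direction=d.get("direction", Direction.UNDIRECTED),
            direction_source=d.get("direction_source"),
            sources=frozenset(d.get("sources", ())),
        )
        for a, b, d in g.edges(data=True)
    }


def merge_fi_network(
    pathway_fis: Iterable[FunctionalInteraction],
    predicted_fis: Iterable[FunctionalInteraction],
) -> nx.Graph:
    """Union of pathway-derived and predicted FIs as one annotated graph.

    On collision, pathway provenance wins and the direction is retained.
    """
    return build_network(list(pathway_fis) + list(predicted_fis))


@dataclass(frozen=True)
class NetworkStats:
    n_nodes: int
    n_edges: int
    mean_degree: float
    max_degree: int
    components: Tuple[int, ...]  # sizes, descending

    def as_dict(self) -> Dict[str, object]:
        return {
            "n_nodes": self.n_nodes,
            "n_edges": self.n_edges,
            "mean_degree": self.mean_degree,
            "max_degree": self.max_degree,
            "components": list(self.components),
        }


def network_stats(g: nx.Graph) -> NetworkStats:
    degrees = [d for _, d in g.degree()]
    comps = tuple(
        sorted((len(c) for c in nx.connected_components(g)), reverse=True)
    )
    n = g.number_of_nodes()
    return NetworkStats(
        n_nodes=n,
        n_edges=g.number_of_edges(),
        mean_degree=(sum(degrees) / n) if n else 0.0,
        max_degree=max(degrees, default=0),
        components=comps,
    )


def cc_sharing_rate(
    edges: Iterable[Tuple[str, str]],
    go_cc: Dict[str, Set[str]],
) -> Tuple[float, int]:
    """Fraction of evaluable edges whose endpoints share a cellular-
    component term.

    An edge is evaluable only when both endpoints carry at least one CC
    annotation; edges with an unannotated endpoint stay out of the
    denominator.  Returns (rate, number of evaluable edges).
    """
    evaluable = 0
    shared = 0
    for a, b in edges:
        ta = go_cc.get(a)
        tb = go_cc.get(b)
        if not ta or not tb:
            continue
        evaluable += 1
        if ta & tb:
            shared += 1
    if evaluable == 0:
        raise ValueError("no edges with both endpoints CC-annotated")
    return shared / evaluable, evaluable


def map_to_gene_symbols(
    g: nx.Graph, symbol_map: Dict[str, str]
) -> nx.Graph:
    """Accession-level network -> gene-symbol network.

    Unmapped accessions are dropped (with a logged count); edges are
    re-deduplicated after mapping and self-edges arising from shared
    symbols are discarded.
    """
    out = nx.Graph()
    dropped = {n for n in g.nodes if n not in symbol_map}
    if dropped:
        logger.info("dropping %d unmapped accessions", len(dropped))
    for a, b, data in g.edges(data=True):
        if a in dropped or b in dropped:
            continue
        sa, sb = symbol_map[a].upper(), symbol_map[b].upper()
        if sa == sb:
            continue
        if out.has_edge(sa, sb):
            out[sa][sb]["sources"] = set(out[sa][sb].get("sources", set())) | set(
                data.get("sources", set())
            )
            if data.get("provenance") == "pathway":
                out[sa][sb]["provenance"] = "pathway"
        else:
            out.add_edge(sa, sb, **{k: v for k, v in data.items()})
    return out


def largest_component(g: nx.Graph) -> nx.Graph:
    """Subgraph view copy of the largest connected component."""
    if g.number_of_nodes() == 0:
        return nx.Graph()
    nodes = max(nx.connected_components(g), key=lambda c: (len(c), sorted(c)))
    return g.subgraph(nodes).copy()
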