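"""SNP network construction from selected low-order interactions.

Each selected pair contributes its edge directly; each selected triple
(SNP1, SNP2, SNP3) contributes the three pairwise edges SNP1-SNP2,
SNP1-SNP3, SNP2-SNP3 - the triple's strong joint effect is taken as
evidence for all its pairwise links.  The result is a simple undirected
graph; duplicate edges are merged with their provenance tags unioned.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import networkx as nx

from .scoring import RankedInteractionList

__all__ = ["SNPNetwork", "build_network"]


@dataclass
class SNPNetwork:
    """Simple undirected graph over SNP indices with per-edge provenance."""

    graph: nx.Graph

    @property
    def nodes(self) -> set[int]:
        return set(self.graph.nodes)

    @property
    def edges(self) -> set[tuple[int, int]]:
        return {(min(u, v), max(u, v)) for u, v in self.graph.edges}

    def __len__(self) -> int:
        return self.graph.number_of_nodes()

    def provenance(self, u: int, v: int) -> frozenset[str]:
        """Which interaction orders ('pair', 'triple') produced edge (u, v)."""
        return frozenset(self.graph.edges[u, v]["provenance"])

    def write_edgelist_tsv(self, path, snp_ids=None) -> None:
        name = (lambda i: snp_ids[i]) if snp_ids is not None else str
        with open(path, "w") as fh:
            fh.write("snp_id_a\tsnp_id_b\tprovenance\n")
            for u, v in sorted(self.edges):
                tags = ",".join(sorted(self.provenance(u, v)))
                fh.write(f"{name(u)}\t{name(v)}\t{tags}\n")

    def write_graphml(self, path, snp_ids=None) -> None:
        g = nx.Graph()
        name = (lambda i: snp_ids[i]) if snp_ids is not None else str
        for u, v in self.graph.edges:
            g.add_edge(
                name(u), name(v), provenance=",".join(sorted(self.provenance(u, v)))
            )
        nx.write_graphml(g, path)


def _index_tuples(obj) -> list[tuple[int, ...]]:
    if obj is None:
        return []
    if isinstance(obj, RankedInteractionList):
        return obj.index_tuples()
    return [tuple(int(s) for s in t) for t in obj]


def build_network(pairs, triples) -> SNPNetwork:
    """Build the SNP network from selected order-2 and order-3 interactions.

    ``pairs`` and ``triples`` may be :class:`RankedInteractionList` objects
    (typically the ``selected`` prefix of a threshold result) or plain
    iterables of index tuples.  Nodes are exactly the edge endpoints; the
    construction is order-independent.
    """
    g = nx.Graph()

    def _add(u: int, v: int, tag: str) -> None:
        if u == v:
            raise ValueError(f"self-loop on SNP {u}")
        if g.has_edge(u, v):
            g.edges[u, v]["provenance"].add(tag)
        else:
            g.add_edge(u, v, provenance={tag})

    for pair in _index_tuples(pairs):
        if len(pair) != 2:
            raise ValueError(f"not a pair: {pair}")
        _add(pair[0], pair[1], "pair")
    for triple in _index_tuples(triples):
        if len(triple) != 3:
            raise ValueError(f"not a triple: {triple}")
        for u, v in combinations(triple, 2):
            _add(u, v, "triple")
    return SNPNetwork(graph=g)
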