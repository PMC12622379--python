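"""Evidence-tagged interaction network.

The central in-memory container of the pipeline: an undirected graph over the
reference genome's proteins in which every edge carries a non-empty *evidence
set* recording which genomic signal supports it — ``neighbourhood`` (conserved
chromosomal adjacency across the panel) or ``profile`` (matching phylogenetic
presence/absence pattern) — plus a positive weight (1.0 unless a caller says
otherwise; downstream analyses treat the graph as unweighted by default).

Implemented as a thin veneer over :class:`networkx.Graph` so that standard
graph algorithms apply directly via :attr:`EvidenceNetwork.graph`.
"""

from __future__ import annotations

from collections.abc import Iterable, Iterator

import networkx as nx

from .errors import ValidationError

#: The genomic-context signals an edge may carry.
EVIDENCE_KINDS = frozenset({"neighbourhood", "profile"})


class EvidenceNetwork:
    """Undirected protein network with per-edge evidence sets.

    Invariants enforced on mutation: no self-loops, evidence sets are
    non-empty subsets of :data:`EVIDENCE_KINDS`, weights are positive.
    Re-adding an existing edge merges by evidence-set union (the weight of
    the first insertion is kept).
    """

    def __init__(self) -> None:
        self._g = nx.Graph()

    # -- construction -----------------------------------------------------

    def add_node(self, node: str) -> None:
        self._g.add_node(node)

    def add_edge(
        self,
        a: str,
        b: str,
        evidence: Iterable[str],
        weight: float = 1.0,
    ) -> None:
        if a == b:
            raise ValidationError(f"self-loop not allowed: {a!r}")
        ev = frozenset(evidence)
        if not ev:
            raise ValidationError(f"edge {a!r}-{b!r} has empty evidence set")
        unknown = ev - EVIDENCE_KINDS
        if unknown:
            raise ValidationError(
                f"unknown evidence token(s) {sorted(unknown)} on edge {a!r}-{b!r}"
            )
        if weight <= 0:
            raise ValidationError(f"edge {a!r}-{b!r} has non-positive weight {weight}")
        if self._g.has_edge(a, b):
            ev = ev | self._g.edges[a, b]["evidence"]
            weight = self._g.edges[a, b]["weight"]
        self._g.add_edge(a, b, evidence=ev, weight=float(weight))

    # -- inspection -------------------------------------------------------

    @property
    def graph(self) -> nx.Graph:
        """The underlying :class:`networkx.Graph` (edges carry ``evidence``
        and ``weight`` attributes). Mutate through the wrapper, not here."""
        return self._g

    def nodes(self) -> list[str]:
        return list(self._g.nodes)

    def edges(self) -> Iterator[tuple[str, str, frozenset]]:
        for a, b, data in self._g.edges(data=True):
            yield a, b, data["evidence"]

    def evidence(self, a: str, b: str) -> frozenset:
        return self._g.edges[a, b]["evidence"]

    def has_node(self, node: str) -> bool:
        return self._g.has_node(node)

    def has_edge(self, a: str, b: str) -> bool:
        return self._g.has_edge(a, b)

    def degree(self, node: str) -> int:
        return self._g.degree(node)

    def number_of_nodes(self) -> int:
        return self._g.number_of_nodes()

    def number_of_edges(self) -> int:
        return self._g.number_of_edges()

    def neighbors(self, node: str) -> list[str]:
        return list(self._g.neighbors(node))

    def evidence_counts(self) -> dict[str, int]:
        """Number of edges carrying each evidence tag (an edge with both tags
        counts once per tag)."""
        counts = {kind: 0 for kind in sorted(EVIDENCE_KINDS)}
        for _, _, ev in self.edges():
            for kind in ev:
                counts[kind] += 1
        return counts

    # -- derivation -------------------------------------------------------

    def copy(self) -> "EvidenceNetwork":
        out = EvidenceNetwork()
        out._g = self._g.copy()
        return out

    def subgraph(self, nodes: Iterable[str]) -> "EvidenceNetwork":
        """Induced subgraph on ``nodes`` (deep copy; safe to mutate)."""
        out = EvidenceNetwork()
        out._g = self._g.subgraph(nodes).copy()
        return out

    def remove_edge(self, a: str, b: str) -> None:
        self._g.remove_edge(a, b)

    def remove_node(self, node: str) -> None:
        self._g.remove_node(node)

    # -- equality (node set + edge set + evidence sets) -------------------

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, EvidenceNetwork):
            return NotImplemented
        if set(self._g.nodes) != set(other._g.nodes):
            return False
        mine = {frozenset((a, b)): ev for a, b, ev in self.edges()}
        theirs = {frozenset((a, b)): ev for a, b, ev in other.edges()}
        return mine == theirs

    def __repr__(self) -> str:  # pragma: no cover
        return (
            f"EvidenceNetwork(nodes={self.number_of_nodes()}, "
            f"edges={self.number_of_edges()})"
        )

    @classmethod
    def from_nx(cls, g: nx.Graph, default_evidence: Iterable[str] = ("profile",)) -> "EvidenceNetwork":
        """Wrap an existing undirected graph, filling in a default evidence
        tag where the attribute is absent."""
        out = cls()
        default = frozenset(default_evidence)
        for n in g.nodes:
            out.add_node(str(n))
        for a, b, data in g.edges(data=True):
            ev = data.get("evidence", default)
            out.add_edge(str(a), str(b), ev, weight=float(data.get("weight", 1.0)))
        return out
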