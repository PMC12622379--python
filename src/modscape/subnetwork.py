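"""Target-seeded subnetwork extraction with operon-only-edge exclusion.

The analysis zooms from the whole-proteome network onto the proteins around a
curated target set (e.g. the canonical methane-metabolism machinery): the
subnetwork is the induced subgraph on the targets plus their distance-1
neighbours. Edges supported *only* by conserved neighbourhood whose endpoints
also share a predicted operon are then removed — co-localisation inside one
operon without independent phylogenetic-profile support is weak evidence of a
specific functional link — and non-target neighbours orphaned by that
exclusion are pruned and reported.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .errors import ValidationError
from .io_formats import OperonMap
from .network import EvidenceNetwork


@dataclass
class TargetSet:
    """The seed proteins, optionally labelled with gene symbols."""

    protein_ids: set[str]
    labels: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.protein_ids:
            raise ValidationError("target set is empty")


@dataclass
class SubnetworkResult:
    network: EvidenceNetwork
    filtered_proteins: list[str]
    report: dict[str, str]  # protein -> reason code
    missing_targets: list[str]
    removed_edges: list[tuple[str, str]]


def extract_target_subnetwork(
    net: EvidenceNetwork,
    targets: TargetSet,
    operons: OperonMap | None = None,
    operon_filter_scope: str = "all",
) -> SubnetworkResult:
    """Induce the distance-1 ego network of the targets, then apply the
    operon-only exclusion.

    Steps: (1) induce the subgraph on targets plus all their immediate
    neighbours (edges between two included neighbours are retained); (2)
    remove every edge whose evidence is exactly ``{neighbourhood}`` and whose
    endpoints share an operon id — with ``operon_filter_scope="target-incident"``
    only when one endpoint is a target; (3) drop non-target nodes left with
    degree 0, recording them with reason ``operon-only-orphan``. Targets are
    never dropped. Targets absent from ``net`` are reported, not fatal.
    """
    if operon_filter_scope not in ("all", "target-incident"):
        raise ValidationError(
            f"operon_filter_scope must be 'all' or 'target-incident', "
            f"got {operon_filter_scope!r}"
        )
    operons = operons or OperonMap()
    present = {t for t in targets.protein_ids if net.has_node(t)}
    missing = sorted(targets.protein_ids - present)

    keep = set(present)
    for t in present:
        keep.update(net.neighbors(t))
    sub = net.subgraph(keep)

    removed: list[tuple[str, str]] = []
    for a, b, ev in list(sub.edges()):
        if ev != frozenset({"neighbourhood"}):
            continue
        if not operons.same_operon(a, b):
            continue
        if operon_filter_scope == "target-incident" and not (
            a in present or b in present
        ):
            continue
        removed.append((a, b))
    for a, b in removed:
        sub.remove_edge(a, b)

    report: dict[str, str] = {}
    filtered: list[str] = []
    for node in sorted(sub.nodes()):
        if node in present:
            continue
        if sub.degree(node) == 0:
            filtered.append(node)
            report[node] = "operon-only-orphan"
    for node in filtered:
        sub.remove_node(node)

    return SubnetworkResult(
        network=sub,
        filtered_proteins=filtered,
        report=report,
        missing_targets=missing,
        removed_edges=sorted(removed),
    )
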