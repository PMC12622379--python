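"""Louvain community detection with a resolution parameter.

Modules are found by greedy maximization of resolution-scaled Newman
modularity

    Q(gamma) = sum_c [ e_c / m  -  gamma * (d_c / 2m)^2 ]

where ``e_c`` is the weight of edges inside community ``c``, ``d_c`` the sum
of its members' (weighted) degrees, and ``m`` the total edge weight. The
resolution ``gamma`` scales the configuration-null term (Reichardt–Bornholdt
convention, the lineage Gephi implements): gamma = 1 is standard Newman
modularity; smaller gamma favours fewer, larger modules.

The Louvain optimizer is the standard two-phase scheme — seeded-random local
moving until no gain, then aggregation of communities into supernodes,
repeated until the partition stabilizes. Determinism contract: the node visit
order is the only randomness, driven by the given seed; ties in gain keep the
current community, then take the smallest candidate label; every accepted
move strictly increases Q (asserted during iteration). The same seed always
returns the identical partition.

Because the printed resolution of any published analysis is an empirical
choice, :func:`resolution_sweep` reproduces the selection procedure: scan a
gamma grid, repeat clustering per gamma, and pick the smallest gamma that
consistently yields a small number of large modules.
"""

from __future__ import annotations

import logging
import random
import statistics
from dataclasses import dataclass, field
from typing import Mapping

import networkx as nx

from .errors import ValidationError
from .network import EvidenceNetwork

logger = logging.getLogger(__name__)

_GAIN_EPS = 1e-12  # strict-improvement threshold for local moves


def _as_nx(net: EvidenceNetwork | nx.Graph) -> nx.Graph:
    return net.graph if isinstance(net, EvidenceNetwork) else net


# ---------------------------------------------------------------------------
# Modularity
# ---------------------------------------------------------------------------

def modularity(
    net: EvidenceNetwork | nx.Graph,
    assignment: Mapping,
    gamma: float = 1.0,
    weighted: bool = False,
) -> float:
    """Resolution-scaled Newman modularity of a partition.

    Unweighted by default (every edge counts 1, matching networks whose
    weights are nominal); pass ``weighted=True`` to use edge ``weight``
    attributes. Self-loops contribute their weight to ``e_c`` and twice it to
    ``d_c``.
    """
    g = _as_nx(net)
    for node in g.nodes:
        if node not in assignment:
            raise ValidationError(f"node {node!r} missing from assignment")
    wattr = "weight" if weighted else None
    m = g.size(weight=wattr)
    if m < 1e-300:
        raise ValidationError("modularity undefined for a network with no edges")
    internal: dict = {}
    degree_sum: dict = {}
    for node, deg in g.degree(weight=wattr):
        c = assignment[node]
        degree_sum[c] = degree_sum.get(c, 0.0) + deg
    for a, b, data in g.edges(data=True):
        w = data.get("weight", 1.0) if weighted else 1.0
        if assignment[a] == assignment[b]:
            internal[assignment[a]] = internal.get(assignment[a], 0.0) + w
    q = 0.0
    for c, d_c in degree_sum.items():
        q += internal.get(c, 0.0) / m - gamma * (d_c / (2.0 * m)) ** 2
    return q


# ---------------------------------------------------------------------------
# Louvain
# ---------------------------------------------------------------------------

@dataclass
class ModulePartition:
    """A node -> module assignment with the resolution and score behind it."""

    assignment: dict
    resolution: float
    modularity: float
    seed: int

    def __post_init__(self) -> None:
        labels = sorted(set(self.assignment.values()))
        if labels != list(range(len(labels))):
            raise ValidationError("module labels must be contiguous from 0")

    @property
    def n_modules(self) -> int:
        return len(set(self.assignment.values()))

    def modules(self) -> dict[int, set]:
        out: dict[int, set] = {}
        for node, label in self.assignment.items():
            out.setdefault(label, set()).add(node)
        return out

    def module_sizes(self) -> dict[int, int]:
        return {label: len(nodes) for label, nodes in self.modules().items()}


def _one_level(
    adj: list[dict[int, float]],
    self_w: list[float],
    gamma: float,
    m: float,
    rng: random.Random,
) -> tuple[list[int], bool]:
    """One round of local moving on an integer-indexed graph.

    ``adj[i]`` maps neighbour -> edge weight (no self entries); ``self_w[i]``
    is the node's self-loop weight (internal weight of an aggregated
    community). Returns (community labels, whether any move happened).
    """
    n = len(adj)
    deg = [2.0 * self_w[i] + sum(adj[i].values()) for i in range(n)]
    comm = list(range(n))
    sigma_tot = deg[:]  # sum of degrees per community
    order = list(range(n))
    rng.shuffle(order)
    moved_any = False
    improved = True
    while improved:
        improved = False
        for node in order:
            c_old = comm[node]
            k = deg[node]
            # weight from node to each neighbouring community
            links: dict[int, float] = {}
            for nb, w in adj[node].items():
                links[comm[nb]] = links.get(comm[nb], 0.0) + w
            sigma_tot[c_old] -= k
            # gain (up to a candidate-independent constant) of joining c
            def gain(c: int) -> float:
                return links.get(c, 0.0) / m - gamma * sigma_tot[c] * k / (2.0 * m * m)

            best_c, best_gain = c_old, gain(c_old)
            for c in sorted(links):
                if c == c_old:
                    continue
                g = gain(c)
                # strict improvement required; ties keep current community
                # (checked first) then the smallest label (sorted scan)
                if g > best_gain + _GAIN_EPS:
                    best_c, best_gain = c, g
            assert best_c == c_old or best_gain > gain(c_old) + _GAIN_EPS
            sigma_tot[best_c] += k
            if best_c != c_old:
                comm[node] = best_c
                improved = True
                moved_any = True
    return comm, moved_any


def _aggregate(
    adj: list[dict[int, float]],
    self_w: list[float],
    comm: list[int],
) -> tuple[list[dict[int, float]], list[float], dict[int, int]]:
    """Collapse communities into supernodes; returns the new graph and the
    old-community -> new-index relabeling."""
    labels = sorted(set(comm))
    relabel = {c: i for i, c in enumerate(labels)}
    n_new = len(labels)
    new_adj: list[dict[int, float]] = [dict() for _ in range(n_new)]
    new_self = [0.0] * n_new
    for i in range(len(adj)):
        ci = relabel[comm[i]]
        new_self[ci] += self_w[i]
        for j, w in adj[i].items():
            if j <= i:
                continue  # each undirected edge once
            cj = relabel[comm[j]]
            if ci == cj:
                new_self[ci] += w
            else:
                new_adj[ci][cj] = new_adj[ci].get(cj, 0.0) + w
                new_adj[cj][ci] = new_adj[cj].get(ci, 0.0) + w
    return new_adj, new_self, relabel


def louvain(
    net: EvidenceNetwork | nx.Graph,
    gamma: float = 1.0,
    seed: int = 0,
    weighted: bool = False,
    restarts: int = 1,
) -> ModulePartition:
    """Two-phase Louvain maximization of Q(gamma).

    Deterministic for a fixed seed. The returned labels are contiguous small
    integers, numbered by first appearance over the sorted node ids, so
    relabeling is stable across runs and node permutations.

    Greedy local moving can stall in a local optimum; ``restarts > 1`` runs
    the optimizer with seeds ``seed .. seed+restarts-1`` and keeps the
    highest-Q partition (still fully deterministic). The reported
    :attr:`ModulePartition.seed` is the winning restart's seed.
    """
    if gamma <= 0:
        raise ValidationError("gamma must be > 0")
    if restarts < 1:
        raise ValidationError("restarts must be >= 1")
    if restarts > 1:
        best = None
        for r in range(restarts):
            cand = louvain(net, gamma=gamma, seed=seed + r, weighted=weighted)
            if best is None or cand.modularity > best.modularity + _GAIN_EPS:
                best = cand
        return best
    g = _as_nx(net)
    if g.number_of_nodes() == 0:
        raise ValidationError("empty network")
    nodes = sorted(g.nodes)
    index = {node: i for i, node in enumerate(nodes)}
    adj: list[dict[int, float]] = [dict() for _ in nodes]
    self_w = [0.0] * len(nodes)
    wattr = "weight" if weighted else None
    for a, b, data in g.edges(data=True):
        w = data.get("weight", 1.0) if weighted else 1.0
        if a == b:
            self_w[index[a]] += w
        else:
            adj[index[a]][index[b]] = adj[index[a]].get(index[b], 0.0) + w
            adj[index[b]][index[a]] = adj[index[b]].get(index[a], 0.0) + w
    m = g.size(weight=wattr)
    if m < 1e-300:
        # no edges: every node its own module, Q undefined -> reported as 0
        assignment = {node: i for i, node in enumerate(nodes)}
        return ModulePartition(assignment, gamma, 0.0, seed)

    rng = random.Random(seed)
    membership = list(range(len(nodes)))  # original node -> current supernode
    while True:
        comm, moved = _one_level(adj, self_w, gamma, m, rng)
        if not moved:
            break
        adj, self_w, relabel = _aggregate(adj, self_w, comm)
        membership = [relabel[comm[i]] for i in membership]
        if len(adj) == 1:
            break

    # contiguous labels by first appearance over sorted node ids
    relabel2: dict[int, int] = {}
    assignment: dict = {}
    for node in nodes:
        c = membership[index[node]]
        if c not in relabel2:
            relabel2[c] = len(relabel2)
        assignment[node] = relabel2[c]
    q = modularity(g, assignment, gamma, weighted=weighted)
    return ModulePartition(assignment, gamma, q, seed)


# ---------------------------------------------------------------------------
# Resolution sweep
# ---------------------------------------------------------------------------

@dataclass
class SweepResult:
    """Per-gamma statistics of repeated Louvain runs and the selected value."""

    grid: list[float]
    median_modules: list[float]
    median_modularity: list[float]
    median_coverage: list[float]
    selected_gamma: float
    selection_rule: dict = field(default_factory=dict)
    fallback: bool = False


def resolution_sweep(
    net: EvidenceNetwork | nx.Graph,
    grid: list[float],
    repeats: int = 10,
    max_modules: int = 6,
    min_size: int = 20,
    min_coverage: float = 0.9,
    seed: int = 0,
) -> SweepResult:
    """Empirical resolution selection.

    For each gamma of the ascending grid, run Louvain ``repeats`` times with
    derived seeds and record the median module count, median modularity and
    median coverage (fraction of nodes inside modules of size >= ``min_size``).
    Selected gamma = the smallest one whose median module count is at most
    ``max_modules`` and median coverage at least ``min_coverage``; when none
    qualifies, fall back (with a warning) to the gamma maximizing median
    modularity.
    """
    if not grid:
        raise ValidationError("empty resolution grid")
    if sorted(grid) != list(grid):
        raise ValidationError("grid must be sorted ascending")
    if repeats < 1:
        raise ValidationError("repeats must be >= 1")
    n_nodes = _as_nx(net).number_of_nodes()
    med_mod, med_q, med_cov = [], [], []
    for gi, gamma in enumerate(grid):
        counts, qs, covs = [], [], []
        for r in range(repeats):
            part = louvain(net, gamma=gamma, seed=seed + 1009 * gi + r)
            sizes = part.module_sizes().values()
            counts.append(len(sizes))
            qs.append(part.modularity)
            covs.append(sum(s for s in sizes if s >= min_size) / n_nodes)
        med_mod.append(statistics.median(counts))
        med_q.append(statistics.median(qs))
        med_cov.append(statistics.median(covs))
    selected = None
    for gamma, nm, cov in zip(grid, med_mod, med_cov):
        if nm <= max_modules and cov >= min_coverage:
            selected = gamma
            break
    fallback = selected is None
    if fallback:
        selected = grid[max(range(len(grid)), key=lambda i: med_q[i])]
        logger.warning(
            "no gamma met the selection criteria (max_modules=%d, min_size=%d, "
            "min_coverage=%.2f); falling back to gamma=%.3f (max median modularity)",
            max_modules, min_size, min_coverage, selected,
        )
    return SweepResult(
        grid=list(grid),
        median_modules=med_mod,
        median_modularity=med_q,
        median_coverage=med_cov,
        selected_gamma=selected,
        selection_rule={
            "max_modules": max_modules,
            "min_size": min_size,
            "min_coverage": min_coverage,
            "repeats": repeats,
            "seed": seed,
        },
        fallback=fallback,
    )
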