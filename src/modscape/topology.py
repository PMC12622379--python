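"""Network characterization: degree statistics, power-law fit, bridging
centrality.

Scale-free-like degree distributions are summarized by the discrete
maximum-likelihood exponent over a user-fixed tail cutoff; bridging
centrality (betweenness times a bridging coefficient that rewards nodes whose
neighbours are themselves low-degree) flags proteins that stitch modules
together.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import networkx as nx
import pandas as pd

from .community import _as_nx
from .errors import DegenerateInputError, ValidationError
from .network import EvidenceNetwork


@dataclass
class DegreeSummary:
    min: int
    median: float
    mean: float
    max: int
    histogram: dict[int, int]


def degree_summary(net: EvidenceNetwork | nx.Graph) -> DegreeSummary:
    """Degree statistics over all network nodes.

    Median convention for even counts: the lower of the two central order
    statistics (keeps integer medians integral).
    """
    g = _as_nx(net)
    if g.number_of_nodes() == 0:
        raise ValidationError("empty network")
    degrees = sorted(d for _, d in g.degree())
    hist: dict[int, int] = {}
    for d in degrees:
        hist[d] = hist.get(d, 0) + 1
    n = len(degrees)
    return DegreeSummary(
        min=degrees[0],
        median=float(degrees[(n - 1) // 2]),
        mean=sum(degrees) / n,
        max=degrees[-1],
        histogram=hist,
    )


def powerlaw_exponent(degrees, x_min: int) -> float:
    """Discrete maximum-likelihood power-law exponent.

        alpha_hat = 1 + n / sum_i ln( d_i / (x_min - 0.5) )

    over the tail d_i >= x_min (the 0.5 shift is the standard continuity
    correction for discrete data). Requires at least 10 tail points; constant
    tails at x_min make the log-sum vanish and raise a degenerate-input error.
    """
    if x_min < 1:
        raise ValidationError("x_min must be >= 1")
    tail = [int(d) for d in degrees if d >= x_min]
    if len(tail) < 10:
        raise ValidationError(
            f"need >= 10 degrees >= x_min={x_min}, got {len(tail)}"
        )
    if len(set(tail)) == 1:
        raise DegenerateInputError(
            "degenerate tail: all degrees equal; the exponent is unidentifiable"
        )
    log_sum = sum(math.log(d / (x_min - 0.5)) for d in tail)
    return 1.0 + len(tail) / log_sum


def bridging_centrality(net: EvidenceNetwork | nx.Graph) -> pd.DataFrame:
    """Per-node degree, betweenness, bridging coefficient and their product.

    Betweenness is the unnormalized shortest-path-pair count (components
    handled independently, as in standard all-pairs counting). The bridging
    coefficient of v is (1/deg(v)) / sum_{u in N(v)} 1/deg(u); isolated nodes
    get 0 with the ``isolated`` flag set. Bridging centrality =
    betweenness x bridging coefficient.
    """
    g = _as_nx(net)
    btw = nx.betweenness_centrality(g, normalized=False)
    rows = []
    for node in sorted(g.nodes, key=str):
        deg = g.degree(node)
        if deg == 0:
            coef, isolated = 0.0, True
        else:
            inv_nb = sum(1.0 / g.degree(u) for u in g.neighbors(node))
            coef, isolated = (1.0 / deg) / inv_nb, False
        rows.append(
            {
                "node": node,
                "degree": deg,
                "betweenness": btw[node],
                "bridging_coefficient": coef,
                "bridging_centrality": btw[node] * coef,
                "isolated": isolated,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "node", "degree", "betweenness", "bridging_coefficient",
            "bridging_centrality", "isolated",
        ],
    ).set_index("node")
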