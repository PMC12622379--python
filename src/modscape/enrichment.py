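"""Module-level pathway enrichment, KO inventories, pathway completeness.

Enrichment follows the classical over-representation scheme: for a module of
M proteins inside a background proteome of N proteins, a pathway annotated to
K background proteins and to k of the module's proteins is scored with the
one-tailed hypergeometric upper tail P[X >= k], X ~ Hypergeometric(N, K, M),
then Benjamini–Hochberg adjusted across the whole family of (module, pathway)
tests. Unannotated proteins count toward M and N but never toward k or K, so
the background N may exceed the number of annotated proteins.

KO inventories give a module's non-redundant functional parts list (unique KO
terms across members); pathway completeness checks which of a pathway's
essential catalytic EC numbers are carried by any background protein and
where the carriers sit in the module partition.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from .community import ModulePartition
from .errors import ValidationError
from .io_formats import AnnotationMap

_P_FLOOR = 5e-324  # smallest positive float; keeps p in (0, 1] under underflow


def hypergeom_upper_tail(k: int, M: int, K: int, N: int) -> float:
    """Exact P[X >= k] for X ~ Hypergeometric(N, K, M).

    ``k`` successes in a module of size ``M``, pathway size ``K``, background
    ``N``. Returns 1.0 when k = 0 (a certain event).
    """
    if not (0 <= K <= N):
        raise ValidationError(f"need 0 <= K <= N, got K={K}, N={N}")
    if not (0 <= M <= N):
        raise ValidationError(f"need 0 <= M <= N, got M={M}, N={N}")
    if not (0 <= k <= min(M, K)):
        raise ValidationError(f"need 0 <= k <= min(M, K), got k={k}, M={M}, K={K}")
    if k == 0:
        return 1.0
    p = float(hypergeom.sf(k - 1, N, K, M))
    return min(max(p, _P_FLOOR), 1.0)


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted q-values, in input order.

    q_(i) = min_{j >= i} ( p_(j) * n / j ), clipped to 1.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or np.any(~np.isfinite(p)):
        raise ValidationError("p-values must lie in [0, 1]")
    n = p.size
    order = np.argsort(p, kind="stable")
    scaled = p[order] * n / np.arange(1, n + 1)
    q_sorted = np.minimum.accumulate(scaled[::-1])[::-1]
    q = np.empty(n)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def enrich_modules(
    partition: ModulePartition,
    ann: AnnotationMap,
    scope: str = "pooled",
    min_K: int = 2,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Hypergeometric over-representation of every pathway in every module.

    One row per (module, pathway) with K >= ``min_K`` background proteins and
    k >= 1 module proteins (a pathway absent from a module cannot be
    over-represented one-tailed). Columns: module, pathway, k, M, K, N,
    p_value, q_value, significant (q < ``alpha``). With ``scope="pooled"``
    (default) the BH family is all emitted tests; with ``scope="per_module"``
    adjustment runs within each module.
    """
    if scope not in ("pooled", "per_module"):
        raise ValidationError(f"scope must be 'pooled' or 'per_module', got {scope!r}")
    if min_K < 1:
        raise ValidationError("min_K must be >= 1")
    N = ann.background_size
    n_nodes = len(partition.assignment)
    if N < n_nodes:
        raise ValidationError(
            f"background_size {N} smaller than partition size {n_nodes}"
        )
    K_of = {pw: K for pw, K in ann.pathway_sizes().items() if K >= min_K}
    rows = []
    for label, members in sorted(partition.modules().items()):
        M = len(members)
        counts: dict[str, int] = {}
        for pid in members:
            for pw in ann.pathway_of.get(pid, ()):
                if pw in K_of:
                    counts[pw] = counts.get(pw, 0) + 1
        for pw in sorted(counts):
            k = counts[pw]
            rows.append(
                {
                    "module": label,
                    "pathway": pw,
                    "k": k,
                    "M": M,
                    "K": K_of[pw],
                    "N": N,
                    "p_value": hypergeom_upper_tail(k, M, K_of[pw], N),
                }
            )
    df = pd.DataFrame(
        rows, columns=["module", "pathway", "k", "M", "K", "N", "p_value"]
    )
    if df.empty:
        df["q_value"] = pd.Series(dtype=float)
        df["significant"] = pd.Series(dtype=bool)
        return df
    if scope == "pooled":
        df["q_value"] = bh_adjust(df["p_value"].to_numpy())
    else:
        df["q_value"] = np.nan
        for label in df["module"].unique():
            mask = df["module"] == label
            df.loc[mask, "q_value"] = bh_adjust(df.loc[mask, "p_value"].to_numpy())
    df["significant"] = df["q_value"] < alpha
    return df


# ---------------------------------------------------------------------------
# KO inventory
# ---------------------------------------------------------------------------

@dataclass
class KOInventory:
    """A module's non-redundant KO parts list."""

    module_label: int | str
    n_proteins: int
    n_with_ko: int
    unique_kos: set[str]
    category_counts: dict[str, int] = field(default_factory=dict)


def ko_inventory(
    module_nodes: set,
    ann: AnnotationMap,
    category_map: dict[str, str] | None = None,
    module_label: int | str = "",
) -> KOInventory:
    """Unique-KO union across member proteins; categories counted by unique
    KO (not by protein) via an optional KO -> category map."""
    with_ko = [pid for pid in module_nodes if ann.ko_of.get(pid)]
    unique: set[str] = set()
    for pid in with_ko:
        unique.update(ann.ko_of[pid])
    categories: dict[str, int] = {}
    if category_map:
        for ko in unique:
            cat = category_map.get(ko, "uncategorized")
            categories[cat] = categories.get(cat, 0) + 1
    return KOInventory(
        module_label=module_label,
        n_proteins=len(module_nodes),
        n_with_ko=len(with_ko),
        unique_kos=unique,
        category_counts=categories,
    )


# ---------------------------------------------------------------------------
# Pathway completeness
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PathwayDefinition:
    """A pathway and the EC numbers of its essential catalytic steps."""

    pathway_id: str
    required_ecs: frozenset

    def __post_init__(self) -> None:
        if not self.required_ecs:
            raise ValidationError(f"pathway {self.pathway_id!r} has no required ECs")


@dataclass
class CompletenessReport:
    pathway_id: str
    required_ecs: set[str]
    present_ecs: dict[str, set]  # EC -> carrier protein ids
    missing_ecs: set[str]
    completeness: float
    module_localisation: dict[str, set]  # EC -> set of module labels / "outside"


def pathway_completeness(
    defn: PathwayDefinition,
    ann: AnnotationMap,
    partition: ModulePartition | None = None,
) -> CompletenessReport:
    """Fraction of a pathway's essential ECs carried by any background
    protein, with module localisation of the carriers.

    An EC counts as present regardless of copy number; a multifunctional
    protein may satisfy several ECs. Carriers outside the partition (or when
    no partition is given) localise to ``"outside"``.
    """
    carriers: dict[str, set] = {}
    for pid, ecs in ann.ec_of.items():
        for ec in ecs & defn.required_ecs:
            carriers.setdefault(ec, set()).add(pid)
    missing = set(defn.required_ecs) - set(carriers)
    localisation: dict[str, set] = {}
    assignment = partition.assignment if partition else {}
    for ec, pids in carriers.items():
        localisation[ec] = {
            assignment[pid] if pid in assignment else "outside" for pid in pids
        }
    return CompletenessReport(
        pathway_id=defn.pathway_id,
        required_ecs=set(defn.required_ecs),
        present_ecs=carriers,
        missing_ecs=missing,
        completeness=len(carriers) / len(defn.required_ecs),
        module_localisation=localisation,
    )


def read_pathway_definitions(path) -> list[PathwayDefinition]:
    """Pathway-definition TSV: ``pathway_id TAB comma-joined ECs``."""
    from pathlib import Path

    defs = []
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        if not raw.strip() or raw.startswith("#"):
            continue
        fields = raw.rstrip("\n").split("\t")
        if len(fields) != 2:
            raise ValidationError(
                f"line {lineno}: expected 'pathway_id<TAB>ec1,ec2,...'"
            )
        ecs = frozenset(t.strip() for t in fields[1].split(",") if t.strip())
        defs.append(PathwayDefinition(fields[0].strip(), ecs))
    return defs
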