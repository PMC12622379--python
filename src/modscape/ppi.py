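"""Genomic-context protein–protein interaction inference.

Desk-scale reimplementation of feature-based genomic-context inference:

1. every protein is summarized as a fixed-length vector of propensity-index
   means (:func:`compute_feature_vector`);
2. cross-genome protein *families* are formed by matching panel proteins to
   reference-genome seeds on feature similarity (:func:`cluster_families`),
   yielding a binary presence/absence *phylogenetic profile* per family;
3. edges are predicted from two independent genomic signals —
   matching profiles (:func:`profile_edges`) and conserved gene
   neighbourhoods (:func:`neighbourhood_edges`) — and merged into one
   evidence-tagged network over the reference proteome
   (:func:`assemble_network`).

The result is a projection onto the reference genome: nodes are reference
proteins, but the supporting evidence is drawn from the whole panel. Inferred
interactions are functional associations (same complex/pathway/process), not
demonstrated physical contacts.

Everything here is deterministic: identical inputs and parameters give
byte-identical edge sets.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ValidationError
from .io_formats import GenomeRecord
from .network import EvidenceNetwork
from .propensity import CANONICAL_RESIDUES, IndexSet, default_index_set

_REL_EPS = 1e-9  # floor for relative-difference denominators


# ---------------------------------------------------------------------------
# Feature vectors
# ---------------------------------------------------------------------------

def compute_feature_vector(sequence: str, index_set: IndexSet) -> np.ndarray:
    """Composition-weighted mean of each propensity index over ``sequence``.

    ``X`` residues take the mean of the 20 canonical values of each index;
    any other non-canonical residue is an error.
    """
    if not sequence:
        raise ValidationError("empty sequence")
    counts = np.zeros(len(CANONICAL_RESIDUES) + 1)  # last slot = X
    res_index = {r: i for i, r in enumerate(CANONICAL_RESIDUES)}
    for i, r in enumerate(sequence):
        if r == "X":
            counts[-1] += 1
        elif r in res_index:
            counts[res_index[r]] += 1
        else:
            raise ValidationError(f"residue {r!r} at offset {i} not in any index table")
    # table matrix: one row per index, one column per canonical residue + X
    mat = np.array(
        [[t[r] for r in CANONICAL_RESIDUES] for t in index_set.tables], dtype=float
    )
    mat = np.hstack([mat, mat.mean(axis=1, keepdims=True)])
    return mat @ counts / len(sequence)


# ---------------------------------------------------------------------------
# Families and profiles
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FeatureSimilarityParams:
    """Match rule for joining a panel protein to a reference seed: at least
    ``min_fraction`` of the features must agree within relative tolerance
    ``delta``."""

    delta: float = 0.05
    min_fraction: float = 0.9

    def __post_init__(self) -> None:
        if not (0 <= self.delta):
            raise ValidationError("delta must be >= 0")
        if not (0 < self.min_fraction <= 1):
            raise ValidationError("min_fraction must be in (0, 1]")


@dataclass
class ProteinFamily:
    """A cross-genome orthology cluster. Seeded families hold exactly one
    reference member; unmatched panel proteins form singleton families."""

    family_id: str
    members: set = field(default_factory=set)  # of (genome_id, protein_id)
    reference_members: set = field(default_factory=set)  # protein ids


def family_id_for_seed(protein_id: str) -> str:
    return f"fam:{protein_id}"


def cluster_families(
    panel: list[GenomeRecord],
    reference_id: str,
    sim: FeatureSimilarityParams | None = None,
    index_set: IndexSet | None = None,
) -> tuple[list[ProteinFamily], pd.DataFrame]:
    """Seed one family per reference protein and assign panel proteins.

    A non-reference protein joins the seeded family whose feature vector it
    matches under ``sim``; ties go to the smallest mean relative difference,
    then the lexicographically smallest family id. Proteins matching no seed
    become singleton families. Returns the families and the profile matrix
    (families x genomes, presence bits).
    """
    sim = sim or FeatureSimilarityParams()
    index_set = index_set or default_index_set()
    by_id = {g.genome_id: g for g in panel}
    if reference_id not in by_id:
        raise ValidationError(f"reference genome {reference_id!r} not in panel")
    reference = by_id[reference_id]

    seed_ids = reference.protein_ids()
    seed_fids = [family_id_for_seed(p) for p in seed_ids]
    seeds = np.array(
        [compute_feature_vector(p.sequence, index_set) for p in reference.proteins]
    )
    # relative differences are taken against max(|seed value|, index spread):
    # composition means of zero-centred scales sit near 0, where a bare
    # relative difference explodes; the residue-value spread of each index is
    # its natural unit there
    index_spread = np.array(
        [
            np.std([table[r] for r in CANONICAL_RESIDUES])
            for table in index_set.tables
        ]
    )
    seed_scale = np.maximum(np.abs(seeds), np.maximum(index_spread, _REL_EPS))

    families = {
        fid: ProteinFamily(fid, members={(reference_id, pid)}, reference_members={pid})
        for fid, pid in zip(seed_fids, seed_ids)
    }
    # lexicographic tie-break order over seed family ids
    lex_order = np.argsort(np.array(seed_fids))

    for genome in panel:
        if genome.genome_id == reference_id:
            continue
        for prot in genome.proteins:
            v = compute_feature_vector(prot.sequence, index_set)
            rel = np.abs(seeds - v) / seed_scale
            frac = (rel <= sim.delta).mean(axis=1)
            ok = frac >= sim.min_fraction
            if ok.any():
                mean_rel = rel.mean(axis=1)
                best = np.inf
                chosen = None
                # scan in lexicographic family-id order so exact ties keep
                # the smaller id
                for idx in lex_order:
                    if ok[idx] and mean_rel[idx] < best:
                        best = mean_rel[idx]
                        chosen = idx
                fid = seed_fids[int(chosen)]
                families[fid].members.add((genome.genome_id, prot.protein_id))
            else:
                fid = f"singleton:{genome.genome_id}:{prot.protein_id}"
                families[fid] = ProteinFamily(
                    fid, members={(genome.genome_id, prot.protein_id)}
                )

    fam_list = [families[fid] for fid in sorted(families)]
    genome_ids = [g.genome_id for g in panel]
    presence = pd.DataFrame(
        0, index=[f.family_id for f in fam_list], columns=genome_ids, dtype=np.int8
    )
    for fam in fam_list:
        for gid, _ in fam.members:
            presence.loc[fam.family_id, gid] = 1
    return fam_list, presence


# ---------------------------------------------------------------------------
# Edge inference
# ---------------------------------------------------------------------------

def profile_edges(
    profiles: pd.DataFrame,
    families: list[ProteinFamily],
    max_hamming: int = 0,
    min_support: int = 3,
    ubiquity_filter: bool = True,
) -> set[tuple[str, str]]:
    """Edges between reference proteins whose family profiles match.

    Two families pair when their presence rows (i) differ in at most
    ``max_hamming`` genomes, (ii) are each present in at least ``min_support``
    genomes, and (iii) — with ``ubiquity_filter`` — are each absent from at
    least one genome (a clique over universal housekeeping families carries no
    signal). Edges connect the families' reference members.
    """
    if max_hamming < 0:
        raise ValidationError("max_hamming must be >= 0")
    if min_support < 1:
        raise ValidationError("min_support must be >= 1")
    ref_fams = [f for f in families if f.reference_members]
    if not ref_fams:
        return set()
    mat = profiles.loc[[f.family_id for f in ref_fams]].to_numpy(dtype=np.int64)
    n_genomes = mat.shape[1]
    support = mat.sum(axis=1)
    eligible = support >= min_support
    if ubiquity_filter:
        eligible &= support <= n_genomes - 1
    # pairwise Hamming distance via inner products
    inner = mat @ mat.T
    hamming = support[:, None] + support[None, :] - 2 * inner
    edges: set[tuple[str, str]] = set()
    idx = np.nonzero(eligible)[0]
    for ii, jj in itertools.combinations(idx, 2):
        if hamming[ii, jj] <= max_hamming:
            for a in ref_fams[ii].reference_members:
                for b in ref_fams[jj].reference_members:
                    if a != b:
                        edges.add(tuple(sorted((a, b))))
    return edges


def neighbourhood_edges(
    panel: list[GenomeRecord],
    families: list[ProteinFamily],
    window: int = 1,
    min_genomes: int = 3,
) -> set[tuple[str, str]]:
    """Edges between reference proteins whose families sit within ``window``
    gene ranks of each other, on the same contig, in at least ``min_genomes``
    distinct genomes of the panel."""
    if window < 1:
        raise ValidationError("window must be >= 1")
    if min_genomes < 1:
        raise ValidationError("min_genomes must be >= 1")
    fam_of: dict[tuple[str, str], str] = {}
    for fam in families:
        for member in fam.members:
            fam_of[member] = fam.family_id
    ref_members: dict[str, set[str]] = {
        f.family_id: set(f.reference_members) for f in families
    }
    support: dict[tuple[str, str], set[str]] = {}
    for genome in panel:
        by_contig: dict[str | None, list] = {}
        for prot in genome.proteins:
            by_contig.setdefault(prot.contig_id, []).append(prot)
        for prots in by_contig.values():
            prots = sorted(prots, key=lambda p: p.position)
            for i, p in enumerate(prots):
                for j in range(i + 1, len(prots)):
                    q = prots[j]
                    if q.position - p.position > window:
                        break
                    fa = fam_of.get((genome.genome_id, p.protein_id))
                    fb = fam_of.get((genome.genome_id, q.protein_id))
                    if fa is None or fb is None or fa == fb:
                        continue
                    key = tuple(sorted((fa, fb)))
                    support.setdefault(key, set()).add(genome.genome_id)
    edges: set[tuple[str, str]] = set()
    for (fa, fb), genomes in support.items():
        if len(genomes) < min_genomes:
            continue
        for a in ref_members.get(fa, ()):
            for b in ref_members.get(fb, ()):
                if a != b:
                    edges.add(tuple(sorted((a, b))))
    return edges


def assemble_network(
    profile_e: set[tuple[str, str]],
    neigh_e: set[tuple[str, str]],
    reference: GenomeRecord,
) -> tuple[EvidenceNetwork, list[str]]:
    """Merge the two edge sets into one evidence-tagged network.

    Nodes are the reference proteins with at least one edge; proteins with
    none are excluded from the network and returned as the isolated list
    (mirrors a connected subset of the proteome carrying all predictions).
    """
    ref_ids = set(reference.protein_ids())
    net = EvidenceNetwork()
    for tag, edge_set in (("profile", profile_e), ("neighbourhood", neigh_e)):
        for a, b in edge_set:
            if a not in ref_ids or b not in ref_ids:
                raise ValidationError(
                    f"edge endpoint not in reference genome: {(a, b)!r}"
                )
            net.add_edge(a, b, {tag})
    connected = set(net.nodes())
    isolated = sorted(ref_ids - connected)
    return net, isolated


@dataclass
class InferenceResult:
    """End-to-end inference output plus the metadata needed to rerun it."""

    network: EvidenceNetwork
    isolated: list[str]
    families: list[ProteinFamily]
    profiles: pd.DataFrame
    params: dict


def infer_network(
    panel: list[GenomeRecord],
    reference_id: str,
    sim: FeatureSimilarityParams | None = None,
    index_set: IndexSet | None = None,
    max_hamming: int = 0,
    min_support: int = 3,
    ubiquity_filter: bool = True,
    window: int = 1,
    min_genomes: int = 3,
) -> InferenceResult:
    """Run the full inference chain (features -> families -> both edge kinds
    -> assembled network) with one call."""
    sim = sim or FeatureSimilarityParams()
    index_set = index_set or default_index_set()
    families, profiles = cluster_families(panel, reference_id, sim, index_set)
    p_edges = profile_edges(profiles, families, max_hamming, min_support, ubiquity_filter)
    n_edges = neighbourhood_edges(panel, families, window, min_genomes)
    reference = next(g for g in panel if g.genome_id == reference_id)
    net, isolated = assemble_network(p_edges, n_edges, reference)
    params = {
        "reference_id": reference_id,
        "delta": sim.delta,
        "min_fraction": sim.min_fraction,
        "index_set_hash": index_set.content_hash,
        "n_indices": len(index_set),
        "max_hamming": max_hamming,
        "min_support": min_support,
        "ubiquity_filter": ubiquity_filter,
        "window": window,
        "min_genomes": min_genomes,
    }
    return InferenceResult(net, isolated, families, profiles, params)
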