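"""Synthetic pangenomes, networks and annotations with known ground truth.

Every pipeline stage is exercised against data whose answer is planted:

* :func:`gen_panel` emits a small pangenome — per-genome protein FASTA-shaped
  records with family presence/absence structure (*profile blocks*: groups of
  families sharing one presence pattern) and conserved *operon blocks*
  (family runs emitted adjacently, in order, in the listed genomes). Member
  sequences descend from a per-family ancestor by i.i.d. substitution.
* :func:`gen_planted_network` samples a planted-partition graph (two-rate
  stochastic block model) with evidence-tagged edges.
* :func:`gen_annotations` sprays pathway labels at a base rate, multiplied by
  an odds factor for planted (module, pathway) enrichments.

All generators are pure functions of (parameters, seed); truth objects are
directly verifiable against the emitted data.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ValidationError
from .io_formats import AnnotationMap, GenomeRecord, OperonMap, ProteinEntry
from .network import EvidenceNetwork
from .propensity import CANONICAL_RESIDUES

REFERENCE_INDEX = 0  # genome 0 of a panel is the reference


@dataclass(frozen=True)
class ProfileBlockSpec:
    """Families sharing one presence pattern: present exactly in ``genomes``."""

    families: tuple[str, ...]
    genomes: frozenset


@dataclass(frozen=True)
class OperonBlockSpec:
    """An ordered family run emitted adjacently in the listed genomes."""

    families: tuple[str, ...]
    genomes: frozenset


@dataclass
class PanelTruth:
    """Planted structure of a generated pangenome."""

    membership: dict  # (genome_id, protein_id) -> family_id
    presence: pd.DataFrame  # family x genome presence bits
    profile_blocks: list[ProfileBlockSpec]
    operon_blocks: list[OperonBlockSpec]
    seed: int


@dataclass
class NetworkTruth:
    """Planted structure of a generated network."""

    labels: dict  # node -> block index
    p_in: float
    p_out: float
    enriched: list = field(default_factory=list)  # (module, pathway, odds)
    seed: int = 0


def genome_id(i: int) -> str:
    return f"G{i:02d}"


def family_id(i: int) -> str:
    return f"F{i:03d}"


def _mutate(seq: str, rate: float, rng: np.random.Generator) -> str:
    if rate == 0:
        return seq
    out = list(seq)
    hits = np.nonzero(rng.random(len(seq)) < rate)[0]
    for i in hits:
        choices = [r for r in CANONICAL_RESIDUES if r != out[i]]
        out[i] = choices[rng.integers(len(choices))]
    return "".join(out)


def gen_panel(
    n_genomes: int,
    n_families: int,
    profile_blocks: list[ProfileBlockSpec] | None = None,
    operon_blocks: list[OperonBlockSpec] | None = None,
    mutation_rate: float = 0.0,
    seed: int = 0,
    presence_prob: float = 0.8,
    length_range: tuple[int, int] = (80, 300),
) -> tuple[list[GenomeRecord], PanelTruth]:
    """Generate a pangenome with planted profile and operon structure.

    Genome ``G00`` is the reference and carries every family (it seeds the
    families downstream inference clusters). Other genomes carry a family
    according to its profile block, or independently with ``presence_prob``.
    Proteins are named ``<genome>_<family>``; each genome is one contig with
    positions 0..n-1; gene order is a seeded shuffle in which operon-block
    members stay adjacent and ordered in their listed genomes.
    """
    if not (0 <= mutation_rate <= 1):
        raise ValidationError("mutation_rate must be in [0, 1]")
    if not (0 < presence_prob <= 1):
        raise ValidationError("presence_prob must be in (0, 1]")
    profile_blocks = list(profile_blocks or [])
    operon_blocks = list(operon_blocks or [])
    rng = np.random.default_rng(seed)
    genomes = [genome_id(i) for i in range(n_genomes)]
    families = [family_id(i) for i in range(n_families)]
    fam_set = set(families)
    genome_set = set(genomes)
    for block in itertools.chain(profile_blocks, operon_blocks):
        unknown = set(block.families) - fam_set
        if unknown:
            raise ValidationError(f"block references unknown families {sorted(unknown)}")
        unknown_g = set(block.genomes) - genome_set
        if unknown_g:
            raise ValidationError(f"block references unknown genomes {sorted(unknown_g)}")

    # presence matrix: blocks override independent sampling; reference all-1
    presence = pd.DataFrame(0, index=families, columns=genomes, dtype=np.int8)
    block_of: dict[str, ProfileBlockSpec] = {}
    for block in profile_blocks:
        for fam in block.families:
            if fam in block_of:
                raise ValidationError(f"family {fam!r} in two profile blocks")
            block_of[fam] = block
    for fam in families:
        if fam in block_of:
            for g in block_of[fam].genomes:
                presence.loc[fam, g] = 1
        else:
            for g in genomes:
                presence.loc[fam, g] = int(rng.random() < presence_prob)
        presence.loc[fam, genomes[REFERENCE_INDEX]] = 1

    # ancestor sequences
    lo, hi = length_range
    ancestors = {
        fam: "".join(
            CANONICAL_RESIDUES[i]
            for i in rng.integers(len(CANONICAL_RESIDUES), size=int(rng.integers(lo, hi + 1)))
        )
        for fam in families
    }

    records: list[GenomeRecord] = []
    membership: dict = {}
    for g in genomes:
        present = [fam for fam in families if presence.loc[fam, g] == 1]
        present_set = set(present)
        # operon blocks conserved in this genome become atomic ordered units
        units: list[tuple[str, ...]] = []
        in_block: set[str] = set()
        for block in operon_blocks:
            if g in block.genomes and all(f in present_set for f in block.families):
                units.append(tuple(block.families))
                in_block.update(block.families)
        units.extend((fam,) for fam in present if fam not in in_block)
        order = rng.permutation(len(units))
        ordered = [fam for i in order for fam in units[i]]
        entries = []
        for pos, fam in enumerate(ordered):
            pid = f"{g}_{fam}"
            entries.append(
                ProteinEntry(
                    pid,
                    _mutate(ancestors[fam], mutation_rate, rng),
                    position=pos,
                    contig_id=None,
                )
            )
            membership[(g, pid)] = fam
        records.append(GenomeRecord(genome_id=g, proteins=entries))

    truth = PanelTruth(
        membership=membership,
        presence=presence,
        profile_blocks=profile_blocks,
        operon_blocks=operon_blocks,
        seed=seed,
    )
    return records, truth


def operon_map_from_truth(truth: PanelTruth, genome: str = "G00") -> OperonMap:
    """Derive a protein -> operon-id map for one genome from the planted
    operon blocks (block index = operon id)."""
    operon_of: dict[str, str] = {}
    for bi, block in enumerate(truth.operon_blocks):
        if genome in block.genomes:
            for fam in block.families:
                operon_of[f"{genome}_{fam}"] = f"OP{bi:02d}"
    return OperonMap(operon_of=operon_of)


def gen_planted_network(
    block_sizes: list[int],
    p_in: float,
    p_out: float,
    seed: int = 0,
    evidence: tuple[str, ...] = ("profile",),
) -> tuple[EvidenceNetwork, NetworkTruth]:
    """Planted-partition (two-rate SBM) network with evidence-tagged edges.

    Within-block pairs connect with ``p_in``, cross-block pairs with
    ``p_out``; every realized edge carries the given evidence tags. All nodes
    are present even when isolated.
    """
    if any(s < 1 for s in block_sizes):
        raise ValidationError("block sizes must be >= 1")
    if not (0 <= p_out < p_in <= 1):
        raise ValidationError("need 0 <= p_out < p_in <= 1")
    rng = np.random.default_rng(seed)
    labels: dict = {}
    nodes: list[str] = []
    for bi, size in enumerate(block_sizes):
        for _ in range(size):
            node = f"n{len(nodes):04d}"
            nodes.append(node)
            labels[node] = bi
    net = EvidenceNetwork()
    for node in nodes:
        net.add_node(node)
    for i, j in itertools.combinations(range(len(nodes)), 2):
        p = p_in if labels[nodes[i]] == labels[nodes[j]] else p_out
        if rng.random() < p:
            net.add_edge(nodes[i], nodes[j], evidence)
    truth = NetworkTruth(labels=labels, p_in=p_in, p_out=p_out, seed=seed)
    return net, truth


def gen_annotations(
    truth: NetworkTruth,
    n_pathways: int,
    base_rate: float,
    enriched: list[tuple[int, str, float]] | None = None,
    seed: int = 0,
) -> AnnotationMap:
    """Annotate nodes to pathways ``P00 .. P{n-1}`` at ``base_rate``,
    multiplied by ``odds`` (capped at 1) for planted (module, pathway, odds)
    triples. Background size = node count."""
    if not (0 < base_rate < 1):
        raise ValidationError("base_rate must be in (0, 1)")
    enriched = list(enriched or [])
    pathways = [f"P{i:02d}" for i in range(n_pathways)]
    pathway_set = set(pathways)
    module_set = set(truth.labels.values())
    boost: dict[tuple[int, str], float] = {}
    for module, pathway, odds in enriched:
        if module not in module_set:
            raise ValidationError(f"planted enrichment names unknown module {module!r}")
        if pathway not in pathway_set:
            raise ValidationError(f"planted enrichment names unknown pathway {pathway!r}")
        if odds < 1:
            raise ValidationError("odds must be >= 1")
        boost[(module, pathway)] = odds
    rng = np.random.default_rng(seed)
    pathway_of: dict[str, set[str]] = {}
    for node in sorted(truth.labels):
        module = truth.labels[node]
        for pw in pathways:
            p = min(1.0, base_rate * boost.get((module, pw), 1.0))
            if rng.random() < p:
                pathway_of.setdefault(node, set()).add(pw)
    truth.enriched = enriched
    return AnnotationMap(
        pathway_of=pathway_of, background_size=len(truth.labels)
    )
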