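"""Readers and writers for every external format the pipeline touches.

Proteome FASTA (one multi-FASTA per genome, records in chromosomal order),
evidence-tagged edge lists (TSV, a Gephi-compatible DOT subset, GraphML),
InterProScan-style annotation tables with pathway identifiers in the final
column, two-column EC/KO maps, and two-column operon maps.

Conventions
-----------
* Gene order is the record order of the proteome FASTA; positions are 0-based
  ranks per contig (nucleotide coordinates and strand are not modelled).
* A contig id may be declared in a FASTA header as a ``contig=<id>`` token in
  the description; otherwise the whole file counts as one contig.
* The protein id is the first whitespace-delimited token of the header.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import pandas as pd
from Bio import SeqIO
from Bio.SeqRecord import SeqRecord
from Bio.Seq import Seq

from .errors import ParseError, ValidationError
from .network import EVIDENCE_KINDS, EvidenceNetwork

logger = logging.getLogger(__name__)

#: 20 canonical residues plus X (unknown).
ALLOWED_RESIDUES = frozenset("ACDEFGHIKLMNPQRSTVWYX")

_CONTIG_RE = re.compile(r"\bcontig=(\S+)")


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ProteinEntry:
    """One protein of a genome: id, sequence, and its 0-based rank within its
    contig (the gene-order proxy used for neighbourhood evidence)."""

    protein_id: str
    sequence: str
    position: int
    contig_id: str | None = None


@dataclass
class GenomeRecord:
    """One genome's proteins in chromosomal order."""

    genome_id: str
    proteins: list[ProteinEntry]

    def __post_init__(self) -> None:
        seen: set[str] = set()
        per_contig: dict[str | None, int] = {}
        for p in self.proteins:
            if p.protein_id in seen:
                raise ValidationError(
                    f"duplicate protein id {p.protein_id!r} in genome {self.genome_id!r}"
                )
            seen.add(p.protein_id)
            if not p.sequence:
                raise ValidationError(
                    f"empty sequence for {p.protein_id!r} in genome {self.genome_id!r}"
                )
            bad = set(p.sequence) - ALLOWED_RESIDUES
            if bad:
                offset = next(i for i, r in enumerate(p.sequence) if r in bad)
                raise ValidationError(
                    f"illegal residue {p.sequence[offset]!r} at offset {offset} "
                    f"in record {p.protein_id!r}"
                )
            expected = per_contig.get(p.contig_id, 0)
            if p.position != expected:
                raise ValidationError(
                    f"non-consecutive position {p.position} for {p.protein_id!r} "
                    f"(expected {expected} on contig {p.contig_id!r})"
                )
            per_contig[p.contig_id] = expected + 1

    def protein_ids(self) -> list[str]:
        return [p.protein_id for p in self.proteins]

    def __len__(self) -> int:
        return len(self.proteins)

    def __getitem__(self, protein_id: str) -> ProteinEntry:
        for p in self.proteins:
            if p.protein_id == protein_id:
                return p
        raise KeyError(protein_id)


@dataclass
class AnnotationMap:
    """Protein-level functional annotation against a fixed background.

    ``background_size`` is the N of the hypergeometric tests — the size of the
    whole proteome, typically larger than the number of annotated proteins
    (unannotated proteins count toward N but never toward K).
    """

    pathway_of: dict[str, set[str]] = field(default_factory=dict)
    ko_of: dict[str, set[str]] = field(default_factory=dict)
    ec_of: dict[str, set[str]] = field(default_factory=dict)
    background_size: int = 0

    def __post_init__(self) -> None:
        annotated = set(self.pathway_of) | set(self.ko_of) | set(self.ec_of)
        if self.background_size < len(annotated):
            raise ValidationError(
                f"background_size {self.background_size} < "
                f"{len(annotated)} distinct annotated proteins"
            )
        for mapping, what in (
            (self.pathway_of, "pathway"),
            (self.ko_of, "KO"),
            (self.ec_of, "EC"),
        ):
            for pid, ids in mapping.items():
                if any(not i for i in ids):
                    raise ValidationError(f"empty {what} id for protein {pid!r}")

    def pathway_sizes(self) -> dict[str, int]:
        """K per pathway: number of background proteins annotated to it."""
        sizes: dict[str, int] = {}
        for ids in self.pathway_of.values():
            for pw in ids:
                sizes[pw] = sizes.get(pw, 0) + 1
        return sizes


@dataclass
class OperonMap:
    """protein id -> predicted operon id; proteins without an entry are not in
    any predicted operon."""

    operon_of: dict[str, str] = field(default_factory=dict)

    def same_operon(self, a: str, b: str) -> bool:
        oa = self.operon_of.get(a)
        return oa is not None and oa == self.operon_of.get(b)


# ---------------------------------------------------------------------------
# Proteome FASTA
# ---------------------------------------------------------------------------

def read_proteome_fasta(path: str | Path, genome_id: str) -> GenomeRecord:
    """Parse a per-genome protein multi-FASTA into a :class:`GenomeRecord`.

    Records are taken in file order; the first whitespace-delimited header
    token is the protein id; a ``contig=<id>`` token in the description, when
    present, declares the contig (adjacency never crosses contigs).
    """
    path = Path(path)
    entries: list[ProteinEntry] = []
    per_contig: dict[str | None, int] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        m = _CONTIG_RE.search(rec.description)
        contig = m.group(1) if m else None
        pos = per_contig.get(contig, 0)
        per_contig[contig] = pos + 1
        entries.append(
            ProteinEntry(rec.id, str(rec.seq).upper(), position=pos, contig_id=contig)
        )
    if not entries:
        raise ValidationError(f"no records in {path}")
    return GenomeRecord(genome_id=genome_id, proteins=entries)


def write_proteome_fasta(record: GenomeRecord, path: str | Path) -> None:
    recs = []
    for p in record.proteins:
        desc = f"contig={p.contig_id}" if p.contig_id is not None else ""
        recs.append(SeqRecord(Seq(p.sequence), id=p.protein_id, description=desc))
    SeqIO.write(recs, str(path), "fasta")


# ---------------------------------------------------------------------------
# Edge lists (TSV / DOT / GraphML)
# ---------------------------------------------------------------------------

_DIALECTS = ("tsv", "dot", "graphml")


def _parse_evidence(token: str, where: str) -> frozenset:
    parts = [t.strip() for t in str(token).split(",") if t.strip()]
    ev = frozenset(parts)
    unknown = ev - EVIDENCE_KINDS
    if unknown:
        raise ValidationError(f"unknown evidence token(s) {sorted(unknown)} ({where})")
    if not ev:
        raise ValidationError(f"empty evidence field ({where})")
    return ev


def read_edge_list(
    path: str | Path,
    dialect: str = "tsv",
    columns: dict[str, str] | None = None,
) -> EvidenceNetwork:
    """Read an evidence-tagged edge list.

    TSV layout: header row with ``node_a  node_b  evidence  [weight]``;
    the evidence field is a comma-joined subset of
    {``neighbourhood``, ``profile``}. ``columns`` remaps header names for
    foreign deposits (e.g. ``{"node_a": "Source", "node_b": "Target"}``).
    Self-loops are dropped (count logged); parallel records merge by
    evidence-set union.
    """
    if dialect not in _DIALECTS:
        raise ValidationError(f"unknown dialect {dialect!r}; expected one of {_DIALECTS}")
    path = Path(path)
    net = EvidenceNetwork()
    dropped = 0
    if dialect == "tsv":
        df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
        colmap = {"node_a": "node_a", "node_b": "node_b",
                  "evidence": "evidence", "weight": "weight"}
        if columns:
            colmap.update(columns)
        for need in ("node_a", "node_b", "evidence"):
            if colmap[need] not in df.columns:
                raise ParseError(f"missing column {colmap[need]!r} in {path}")
        for i, row in df.iterrows():
            a, b = str(row[colmap["node_a"]]), str(row[colmap["node_b"]])
            if a == b:
                dropped += 1
                continue
            ev = _parse_evidence(row[colmap["evidence"]], f"{path} row {i}")
            w = 1.0
            if colmap["weight"] in df.columns and pd.notna(row[colmap["weight"]]):
                w = float(row[colmap["weight"]])
            net.add_edge(a, b, ev, weight=w)
    elif dialect == "dot":
        net, dropped = _read_dot(path)
    else:  # graphml
        g = nx.read_graphml(str(path))
        for n in g.nodes:
            net.add_node(str(n))
        for a, b, data in g.edges(data=True):
            if a == b:
                dropped += 1
                continue
            ev = _parse_evidence(data.get("evidence", ""), f"{path} edge {a}-{b}")
            net.add_edge(str(a), str(b), ev, weight=float(data.get("weight", 1.0)))
    if dropped:
        logger.info("dropped %d self-loop(s) while reading %s", dropped, path)
    return net


def write_edge_list(net: EvidenceNetwork, path: str | Path, dialect: str = "tsv") -> None:
    if dialect not in _DIALECTS:
        raise ValidationError(f"unknown dialect {dialect!r}; expected one of {_DIALECTS}")
    path = Path(path)
    if dialect == "tsv":
        rows = []
        for a, b, ev in sorted(net.edges(), key=lambda e: (e[0], e[1])):
            rows.append(
                {
                    "node_a": a,
                    "node_b": b,
                    "evidence": ",".join(sorted(ev)),
                    "weight": net.graph.edges[a, b]["weight"],
                }
            )
        pd.DataFrame(rows, columns=["node_a", "node_b", "evidence", "weight"]).to_csv(
            path, sep="\t", index=False
        )
        if not rows:  # keep the header for empty networks
            path.write_text("node_a\tnode_b\tevidence\tweight\n")
    elif dialect == "dot":
        _write_dot(net, path)
    else:
        g = nx.Graph()
        for n in net.nodes():
            g.add_node(n)
        for a, b, ev in net.edges():
            g.add_edge(a, b, evidence=",".join(sorted(ev)),
                       weight=net.graph.edges[a, b]["weight"])
        nx.write_graphml(g, str(path))


# Minimal DOT subset (Gephi-compatible): an undirected `graph { ... }` block
# whose statements are either `"node";` or `"a" -- "b" [key="v", ...];`.

_DOT_EDGE_RE = re.compile(
    r'^"(?P<a>[^"]+)"\s*--\s*"(?P<b>[^"]+)"\s*(?:\[(?P<attrs>[^\]]*)\])?\s*;?$'
)
_DOT_NODE_RE = re.compile(r'^"(?P<n>[^"]+)"\s*;?$')
_DOT_ATTR_RE = re.compile(r'(\w+)\s*=\s*"([^"]*)"')


def _write_dot(net: EvidenceNetwork, path: Path) -> None:
    lines = ["graph modscape {"]
    for n in sorted(net.nodes()):
        lines.append(f'  "{n}";')
    for a, b, ev in sorted(net.edges(), key=lambda e: (e[0], e[1])):
        w = net.graph.edges[a, b]["weight"]
        lines.append(
            f'  "{a}" -- "{b}" [evidence="{",".join(sorted(ev))}", weight="{w}"];'
        )
    lines.append("}")
    path.write_text("\n".join(lines) + "\n")


def _read_dot(path: Path) -> tuple[EvidenceNetwork, int]:
    net = EvidenceNetwork()
    dropped = 0
    in_block = False
    for lineno, raw in enumerate(path.read_text().splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("//") or line.startswith("#"):
            continue
        if not in_block:
            if re.match(r"^(strict\s+)?graph\b.*\{$", line):
                in_block = True
                continue
            raise ParseError(f"expected 'graph ... {{' but found {line!r}", line=lineno)
        if line == "}":
            in_block = False
            continue
        m = _DOT_EDGE_RE.match(line)
        if m:
            a, b = m.group("a"), m.group("b")
            attrs = dict(_DOT_ATTR_RE.findall(m.group("attrs") or ""))
            if a == b:
                dropped += 1
                continue
            ev = _parse_evidence(attrs.get("evidence", ""), f"{path}:{lineno}")
            net.add_edge(a, b, ev, weight=float(attrs.get("weight", 1.0)))
            continue
        m = _DOT_NODE_RE.match(line)
        if m:
            net.add_node(m.group("n"))
            continue
        raise ParseError(f"unparseable DOT statement {line!r}", line=lineno)
    if in_block:
        raise ParseError("unterminated graph block (missing '}')")
    return net, dropped


# ---------------------------------------------------------------------------
# Annotation tables
# ---------------------------------------------------------------------------

def read_annotation_table(
    path: str | Path,
    background_size: int,
    ec_path: str | Path | None = None,
    ko_path: str | Path | None = None,
) -> AnnotationMap:
    """Read an InterProScan-style TSV (protein id in column 1, pipe- or
    comma-separated pathway ids in the final column, ``-`` meaning none),
    plus optional two-column EC / KO companion files."""
    pathway_of: dict[str, set[str]] = {}
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        if not raw.strip() or raw.startswith("#"):
            continue
        fields = raw.rstrip("\n").split("\t")
        if len(fields) < 2:
            raise ParseError("expected >= 2 tab-separated columns", line=lineno)
        pid, last = fields[0], fields[-1].strip()
        if last in ("-", ""):
            continue
        ids = {t.strip() for t in re.split(r"[|,]", last) if t.strip()}
        pathway_of.setdefault(pid, set()).update(ids)
    ec_of = read_two_column_map(ec_path) if ec_path else {}
    ko_of = read_two_column_map(ko_path) if ko_path else {}
    return AnnotationMap(
        pathway_of=pathway_of, ko_of=ko_of, ec_of=ec_of, background_size=background_size
    )


def read_two_column_map(path: str | Path) -> dict[str, set[str]]:
    """Two-column TSV (protein id, annotation id); repeated proteins merge by
    set union; comma-joined second columns are split."""
    out: dict[str, set[str]] = {}
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        if not raw.strip() or raw.startswith("#"):
            continue
        fields = raw.rstrip("\n").split("\t")
        if len(fields) != 2:
            raise ParseError("expected exactly 2 tab-separated columns", line=lineno)
        pid, val = fields[0].strip(), fields[1].strip()
        if val in ("-", ""):
            continue
        out.setdefault(pid, set()).update(
            t.strip() for t in val.split(",") if t.strip()
        )
    return out


def read_operon_map(path: str | Path) -> OperonMap:
    """Two-column TSV (protein id, operon id); a protein may appear at most
    once (the mapping is a function)."""
    operon_of: dict[str, str] = {}
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        if not raw.strip() or raw.startswith("#"):
            continue
        fields = raw.rstrip("\n").split("\t")
        if len(fields) != 2:
            raise ParseError("expected exactly 2 tab-separated columns", line=lineno)
        pid, op = fields[0].strip(), fields[1].strip()
        if pid in operon_of and operon_of[pid] != op:
            raise ValidationError(
                f"protein {pid!r} mapped to two operons ({operon_of[pid]!r}, {op!r})"
            )
        operon_of[pid] = op
    return OperonMap(operon_of=operon_of)


def write_operon_map(operons: OperonMap, path: str | Path) -> None:
    lines = [f"{pid}\t{op}" for pid, op in sorted(operons.operon_of.items())]
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))
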