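"""End-to-end pipeline orchestration.

One :class:`RunConfig` drives the whole chain: network inference from a
genome panel (or import of a precomputed edge list), target-seeded
subnetwork extraction, Louvain clustering (fixed resolution or sweep),
pathway enrichment, KO inventories, pathway completeness, and topology
tables. Every run writes its resolved configuration and a log with the
counts that characterize the result (nodes, edges per evidence tag, filtered
proteins, module count and sizes, modularity, significant pathways), so a
reproduction is a log diff.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass
from pathlib import Path

import pandas as pd
import yaml

from . import community, enrichment, ppi, subnetwork, topology
from .errors import ValidationError
from .io_formats import (
    OperonMap,
    read_annotation_table,
    read_edge_list,
    read_operon_map,
    read_proteome_fasta,
    read_two_column_map,
    write_edge_list,
)
from .network import EvidenceNetwork
from .propensity import default_index_set, load_index_set

logger = logging.getLogger(__name__)

_FASTA_SUFFIXES = (".fasta", ".faa", ".fa")


@dataclass
class RunConfig:
    """Serializable configuration of a full run.

    Exactly one of ``panel_dir`` (inference path) or ``edge_list`` (import
    path) must be set.
    """

    out_dir: str = "modscape_run"
    seed: int = 0

    # inputs
    panel_dir: str | None = None
    reference_id: str | None = None
    edge_list: str | None = None
    edge_list_dialect: str = "tsv"

    # inference parameters
    index_set_path: str | None = None
    n_indices: int = 60
    delta: float = 0.05
    min_fraction: float = 0.9
    max_hamming: int = 0
    min_support: int = 3
    ubiquity_filter: bool = True
    window: int = 1
    min_genomes: int = 3

    # subnetwork
    targets_path: str | None = None
    operons_path: str | None = None
    operon_filter_scope: str = "all"

    # clustering
    gamma: float | None = 0.95
    sweep_grid: list[float] | None = None
    sweep_repeats: int = 10
    sweep_max_modules: int = 6
    sweep_min_size: int = 20
    sweep_min_coverage: float = 0.9

    # enrichment
    annotations_path: str | None = None
    ec_path: str | None = None
    ko_path: str | None = None
    ko_categories_path: str | None = None
    background_size: int | None = None
    enrichment_scope: str = "pooled"
    min_K: int = 2
    alpha: float = 0.05
    pathway_defs_path: str | None = None

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValidationError(f"unknown config key(s) {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(
            yaml.safe_dump(dataclasses.asdict(self), sort_keys=True)
        )


def read_targets(path: str | Path) -> subnetwork.TargetSet:
    """Target list: one protein id per line, optional TAB-separated label."""
    ids: set[str] = set()
    labels: dict[str, str] = {}
    for raw in Path(path).read_text().splitlines():
        if not raw.strip() or raw.startswith("#"):
            continue
        fields = raw.rstrip("\n").split("\t")
        ids.add(fields[0].strip())
        if len(fields) > 1 and fields[1].strip():
            labels[fields[0].strip()] = fields[1].strip()
    return subnetwork.TargetSet(protein_ids=ids, labels=labels)


def _load_network(config: RunConfig, out: Path) -> EvidenceNetwork:
    if (config.panel_dir is None) == (config.edge_list is None):
        raise ValidationError(
            "exactly one of panel_dir (inference) or edge_list (import) must be set"
        )
    if config.edge_list is not None:
        net = read_edge_list(config.edge_list, dialect=config.edge_list_dialect)
        logger.info(
            "imported network: %d nodes, %d edges (%s)",
            net.number_of_nodes(), net.number_of_edges(), net.evidence_counts(),
        )
        return net
    panel_dir = Path(config.panel_dir)
    paths = sorted(
        p for p in panel_dir.iterdir() if p.suffix.lower() in _FASTA_SUFFIXES
    )
    if not paths:
        raise ValidationError(f"no FASTA files in {panel_dir}")
    panel = [read_proteome_fasta(p, genome_id=p.stem) for p in paths]
    reference_id = config.reference_id or panel[0].genome_id
    index_set = (
        load_index_set(config.index_set_path)
        if config.index_set_path
        else default_index_set(config.n_indices)
    )
    result = ppi.infer_network(
        panel,
        reference_id,
        sim=ppi.FeatureSimilarityParams(config.delta, config.min_fraction),
        index_set=index_set,
        max_hamming=config.max_hamming,
        min_support=config.min_support,
        ubiquity_filter=config.ubiquity_filter,
        window=config.window,
        min_genomes=config.min_genomes,
    )
    logger.info(
        "inferred network: %d nodes, %d edges (%s), %d isolated proteins; params=%s",
        result.network.number_of_nodes(), result.network.number_of_edges(),
        result.network.evidence_counts(), len(result.isolated), result.params,
    )
    (out / "isolated.txt").write_text("\n".join(result.isolated) + "\n")
    result.profiles.to_csv(out / "profiles.tsv", sep="\t", index_label="family_id")
    return result.network


def _write_partition(part: community.ModulePartition, path: Path) -> None:
    rows = sorted(part.assignment.items())
    pd.DataFrame(rows, columns=["protein_id", "module"]).to_csv(
        path, sep="\t", index=False
    )


def run_pipeline(config: RunConfig) -> Path:
    """Execute every configured stage; returns the run directory."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "run.log")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    root = logging.getLogger("modscape")
    root.addHandler(handler)
    old_level = root.level
    root.setLevel(logging.INFO)
    try:
        config.to_yaml(out / "config_resolved.yaml")
        net = _load_network(config, out)
        write_edge_list(net, out / "network.tsv", dialect="tsv")

        analysis_net = net
        targets = None
        if config.targets_path:
            targets = read_targets(config.targets_path)
            operons = (
                read_operon_map(config.operons_path)
                if config.operons_path
                else OperonMap()
            )
            result = subnetwork.extract_target_subnetwork(
                net, targets, operons, operon_filter_scope=config.operon_filter_scope
            )
            analysis_net = result.network
            logger.info(
                "subnetwork: %d nodes, %d edges; %d filtered proteins; "
                "%d missing targets",
                analysis_net.number_of_nodes(), analysis_net.number_of_edges(),
                len(result.filtered_proteins), len(result.missing_targets),
            )
            write_edge_list(analysis_net, out / "subnet.tsv", dialect="tsv")
            pd.DataFrame(
                sorted(result.report.items()), columns=["protein_id", "reason"]
            ).to_csv(out / "filtered.tsv", sep="\t", index=False)

        if config.sweep_grid:
            sweep = community.resolution_sweep(
                analysis_net,
                grid=config.sweep_grid,
                repeats=config.sweep_repeats,
                max_modules=config.sweep_max_modules,
                min_size=config.sweep_min_size,
                min_coverage=config.sweep_min_coverage,
                seed=config.seed,
            )
            pd.DataFrame(
                {
                    "gamma": sweep.grid,
                    "median_modules": sweep.median_modules,
                    "median_modularity": sweep.median_modularity,
                    "median_coverage": sweep.median_coverage,
                }
            ).to_csv(out / "sweep.tsv", sep="\t", index=False)
            gamma = sweep.selected_gamma
            logger.info("sweep selected gamma=%.3f (fallback=%s)", gamma, sweep.fallback)
        else:
            gamma = config.gamma if config.gamma is not None else 1.0
        part = community.louvain(analysis_net, gamma=gamma, seed=config.seed)
        logger.info(
            "partition: %d modules, sizes=%s, modularity=%.4f at gamma=%.3f (seed=%d)",
            part.n_modules, sorted(part.module_sizes().values(), reverse=True),
            part.modularity, gamma, config.seed,
        )
        _write_partition(part, out / "partition.tsv")

        ann = None
        if config.annotations_path:
            if config.background_size is None:
                raise ValidationError(
                    "background_size is required with annotations_path"
                )
            ann = read_annotation_table(
                config.annotations_path,
                background_size=config.background_size,
                ec_path=config.ec_path,
                ko_path=config.ko_path,
            )
            enr = enrichment.enrich_modules(
                part, ann, scope=config.enrichment_scope,
                min_K=config.min_K, alpha=config.alpha,
            )
            enr.to_csv(out / "enrichment.tsv", sep="\t", index=False)
            logger.info(
                "enrichment: %d tests, %d significant at q<%.2f",
                len(enr), int(enr["significant"].sum()) if len(enr) else 0,
                config.alpha,
            )
            categories = (
                read_two_column_map(config.ko_categories_path)
                if config.ko_categories_path
                else {}
            )
            cat_map = {ko: min(c) for ko, c in categories.items()}
            inv_rows = []
            for label, members in sorted(part.modules().items()):
                inv = enrichment.ko_inventory(members, ann, cat_map, module_label=label)
                inv_rows.append(
                    {
                        "module": label,
                        "n_proteins": inv.n_proteins,
                        "n_with_ko": inv.n_with_ko,
                        "n_unique_kos": len(inv.unique_kos),
                        "unique_kos": ",".join(sorted(inv.unique_kos)),
                    }
                )
            pd.DataFrame(inv_rows).to_csv(out / "ko_inventory.tsv", sep="\t", index=False)
            if config.pathway_defs_path:
                defs = enrichment.read_pathway_definitions(config.pathway_defs_path)
                comp_rows = []
                for defn in defs:
                    rep = enrichment.pathway_completeness(defn, ann, part)
                    comp_rows.append(
                        {
                            "pathway": rep.pathway_id,
                            "completeness": rep.completeness,
                            "present_ecs": ",".join(sorted(rep.present_ecs)),
                            "missing_ecs": ",".join(sorted(rep.missing_ecs)),
                        }
                    )
                pd.DataFrame(comp_rows).to_csv(
                    out / "completeness.tsv", sep="\t", index=False
                )

        summary = topology.degree_summary(analysis_net)
        logger.info(
            "degrees: min=%d median=%g mean=%.2f max=%d",
            summary.min, summary.median, summary.mean, summary.max,
        )
        pd.DataFrame(
            sorted(summary.histogram.items()), columns=["degree", "count"]
        ).to_csv(out / "degree_hist.tsv", sep="\t", index=False)
        topology.bridging_centrality(analysis_net).to_csv(
            out / "centrality.tsv", sep="\t"
        )

        if targets is not None:
            rows = []
            for pid in sorted(targets.protein_ids):
                in_net = analysis_net.has_node(pid)
                rows.append(
                    {
                        "protein_id": pid,
                        "label": targets.labels.get(pid, ""),
                        "degree": analysis_net.degree(pid) if in_net else 0,
                        "module": part.assignment.get(pid, "missing"),
                    }
                )
            pd.DataFrame(rows).to_csv(out / "targets_report.tsv", sep="\t", index=False)
        return out
    finally:
        root.removeHandler(handler)
        root.setLevel(old_level)
        handler.close()
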