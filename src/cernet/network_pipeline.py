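"""Typed ceRNA network assembly, candidate-gene subnetworks, and the
end-to-end pipeline driver.

Networks carry typed nodes (mRNA / miRNA / lncRNA / circRNA, each with a DE
direction where known) and two edge kinds: directed ``mirna_represses``
edges from a miRNA to each of its targets, and ``cerna_coexpression`` edges
between a ceRNA and the mRNA it shadows.  Candidate-gene subnetworks are
built straight from the published association table (gene -> miRNAs /
lncRNAs / circRNAs), which keeps the printed worked example exactly
reproducible.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import pandas as pd
import yaml

from . import cerna_core, diffexpr, io_formats, target_prediction
from .cerna_core import CeRNATriplet
from .io_formats import RNA_CLASSES, AssociationRecord

__all__ = [
    "CeRNANetwork",
    "build_network",
    "subnetwork_for_genes",
    "summarize_nodes",
    "run_pipeline",
]

logger = logging.getLogger("cernet")

MIRNA_REPRESSES = "mirna_represses"
CERNA_COEXPRESSION = "cerna_coexpression"


@dataclass
class CeRNANetwork:
    """Nodes (id, rna_class, de_direction) and typed, deduplicated edges."""

    nodes: list[tuple[str, str, str]] = field(default_factory=list)
    edges: list[tuple[str, str, str, dict]] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [n[0] for n in self.nodes]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate node ids")
        known = set(ids)
        for source, target, _, _ in self.edges:
            if source not in known or target not in known:
                raise ValueError(f"edge endpoint missing: {source}->{target}")
        for _, rna_class, _ in self.nodes:
            if rna_class not in RNA_CLASSES:
                raise ValueError(f"unknown rna_class {rna_class!r}")

    @property
    def node_ids(self) -> set[str]:
        return {n[0] for n in self.nodes}


def build_network(
    triplets: Sequence[CeRNATriplet],
    de_direction: dict[str, str] | None = None,
) -> CeRNANetwork:
    """Assemble accepted triplets into one network.

    Per triplet: miRNA->ce and miRNA->mRNA repression edges and a ce-mRNA
    co-expression edge; nodes and edges are deduplicated, output order is
    deterministic.
    """
    de_direction = de_direction or {}
    node_class: dict[str, str] = {}
    edge_attrs: dict[tuple[str, str, str], dict] = {}
    for t in triplets:
        node_class[t.ce_id] = t.ce_class
        node_class[t.mirna_id] = "miRNA"
        node_class[t.mrna_id] = "mRNA"
        edge_attrs.setdefault(
            (t.mirna_id, t.ce_id, MIRNA_REPRESSES), {"scc": round(t.scc_ce_mirna, 6)}
        )
        edge_attrs.setdefault(
            (t.mirna_id, t.mrna_id, MIRNA_REPRESSES),
            {"scc": round(t.scc_mrna_mirna, 6)},
        )
        edge_attrs.setdefault(
            (t.ce_id, t.mrna_id, CERNA_COEXPRESSION),
            {"pcc": round(t.pcc_ce_mrna, 6), "sponge_p": t.sponge.pvalue},
        )
    nodes = [
        (fid, node_class[fid], de_direction.get(fid, "ns"))
        for fid in sorted(node_class)
    ]
    edges = [
        (source, target, kind, attrs)
        for (source, target, kind), attrs in sorted(
            edge_attrs.items(), key=lambda kv: kv[0]
        )
    ]
    return CeRNANetwork(nodes, edges)


def subnetwork_for_genes(
    associations: Sequence[AssociationRecord], genes: Sequence[str]
) -> CeRNANetwork:
    """Candidate-gene subnetwork from the association table.

    Nodes are the selected genes plus the union of their listed miRNAs,
    lncRNAs and circRNAs (verbatim id matching, deduplicated across genes);
    edges link each gene to each of its listed regulators.
    """
    by_gene = {rec.gene: rec for rec in associations}
    unknown = [g for g in genes if g not in by_gene]
    if unknown:
        raise KeyError(f"gene symbol(s) not in association table: {unknown}")
    node_class: dict[str, str] = {}
    edges: list[tuple[str, str, str, dict]] = []
    seen_edges: set[tuple[str, str, str]] = set()
    for gene in genes:
        rec = by_gene[gene]
        node_class[gene] = "mRNA"
        for rna_class, partners, kind in (
            ("miRNA", rec.mirnas, MIRNA_REPRESSES),
            ("lncRNA", rec.lncrnas, CERNA_COEXPRESSION),
            ("circRNA", rec.circrnas, CERNA_COEXPRESSION),
        ):
            for partner in partners:
                node_class.setdefault(partner, rna_class)
                key = (partner, gene, kind)
                if key not in seen_edges:
                    seen_edges.add(key)
                    edges.append((*key, {}))
    nodes = [(fid, node_class[fid], "ns") for fid in sorted(node_class)]
    edges.sort(key=lambda e: (e[0], e[1], e[2]))
    return CeRNANetwork(nodes, edges)


def summarize_nodes(network: CeRNANetwork) -> dict[str, int]:
    """Node counts per RNA class (every class reported, zeros included)."""
    counts = {c: 0 for c in RNA_CLASSES}
    for _, rna_class, _ in network.nodes:
        counts[rna_class] += 1
    return counts


# ---------------------------------------------------------------------------
# end-to-end driver

DEFAULT_THRESHOLDS = {
    "fc_threshold_log2": diffexpr.FC_THRESHOLD_LOG2,
    "fdr_threshold": diffexpr.FDR_THRESHOLD,
    "scc_threshold": cerna_core.SCC_THRESHOLD,
    "pcc_threshold": cerna_core.PCC_THRESHOLD,
    "sponge_p_threshold": cerna_core.SPONGE_P_THRESHOLD,
    "min_site_type": "7mer-m8",
    "bidirectional_window": 1000,
}


def _combined_log_expression(counts: dict[str, io_formats.CountMatrix]) -> pd.DataFrame:
    frames = [diffexpr.log_expression(m) for m in counts.values()]
    samples = list(frames[0].columns)
    for frame in frames[1:]:
        if list(frame.columns) != samples:
            raise ValueError("sample columns differ between RNA classes")
    return pd.concat(frames, axis=0)


def analyze_counts(
    counts: dict[str, io_formats.CountMatrix],
    sequences: dict[str, str],
    thresholds: dict | None = None,
    universe_u: int | None = None,
):
    """Run DE -> target prediction -> ceRNA filtering on loaded inputs.

    Returns (de_records, target_map, edges, triplets); the building blocks
    ``run_pipeline`` writes to disk.
    """
    opts = {**DEFAULT_THRESHOLDS, **(thresholds or {})}
    de_frames = [
        diffexpr.call_de(
            matrix,
            fc_threshold_log2=opts["fc_threshold_log2"],
            fdr_threshold=opts["fdr_threshold"],
        )
        for matrix in counts.values()
    ]
    de_records = pd.concat(de_frames, axis=0)
    logger.info(
        "DE stage: %d features, %d significant",
        len(de_records),
        int((de_records["status"] != "ns").sum()),
    )

    de_mirnas = sorted(
        de_records.index[
            (de_records["rna_class"] == "miRNA") & (de_records["status"] != "ns")
        ]
    )
    target_ids = [
        fid
        for rna_class in ("mRNA", "lncRNA", "circRNA")
        for fid in counts[rna_class].feature_ids
    ]
    target_map = target_prediction.build_target_map(
        de_mirnas,
        {m: sequences[m] for m in de_mirnas if m in sequences},
        {t: sequences[t] for t in target_ids if t in sequences},
        min_site_type=opts["min_site_type"],
    )
    logger.info("target stage: %d predicted pairs", len(target_map.pairs()))

    expression = _combined_log_expression(counts)
    edges = cerna_core.candidate_pairs(
        target_map, de_records, expression,
        scc_threshold=opts["scc_threshold"],
    )
    logger.info("correlation stage: %d passing miRNA-target edges", len(edges))
    triplets = cerna_core.assemble_triplets(
        edges, expression, de_records, universe_u=universe_u,
        pcc_threshold=opts["pcc_threshold"],
        sponge_p_threshold=opts["sponge_p_threshold"],
    )
    logger.info("triplet stage: %d accepted triplets", len(triplets))
    return de_records, target_map, edges, triplets


def run_pipeline(config_path: str | Path) -> Path:
    """Execute the full analysis described by a YAML config file.

    The config names the four count tables, the condition map, the FASTA of
    transcript sequences, an output directory, and optional threshold
    overrides.  Outputs: per-class DE tables, the site table, the triplet
    table, GraphML + Cytoscape edge table, and a run log with thresholds
    and stage counts.  Identical config and inputs give identical outputs.
    """
    config_path = Path(config_path)
    with open(config_path) as fh:
        config = yaml.safe_load(fh)
    base = config_path.parent
    outdir = Path(config["output_dir"])
    if not outdir.is_absolute():
        outdir = base / outdir
    outdir.mkdir(parents=True, exist_ok=True)

    counts = {
        rna_class: io_formats.load_counts(
            base / config["counts"][rna_class],
            base / config["condition_map"],
            rna_class,
        )
        for rna_class in RNA_CLASSES
    }
    sequences = io_formats.load_fasta(base / config["sequences"])
    thresholds = {**DEFAULT_THRESHOLDS, **config.get("thresholds", {})}

    de_records, target_map, edges, triplets = analyze_counts(
        counts, sequences, thresholds, universe_u=config.get("universe_u")
    )

    for rna_class in RNA_CLASSES:
        diffexpr.write_de_table(
            de_records[de_records["rna_class"] == rna_class],
            outdir / f"de_{rna_class}.tsv",
        )
    target_prediction.write_site_table(target_map, outdir / "sites.tsv")
    cerna_core.write_triplet_table(triplets, outdir / "triplets.tsv")

    de_direction = {
        fid: status
        for fid, status in de_records["status"].items()
        if status != "ns"
    }
    network = build_network(triplets, de_direction)
    io_formats.export_network(network, outdir)

    with open(outdir / "run_log.txt", "w") as fh:
        fh.write(f"config: {config_path.name}\n")
        for key in sorted(thresholds):
            fh.write(f"threshold {key}: {thresholds[key]}\n")
        fh.write(f"features: {sum(len(m.feature_ids) for m in counts.values())}\n")
        fh.write(f"de_features: {int((de_records['status'] != 'ns').sum())}\n")
        fh.write(f"target_pairs: {len(target_map.pairs())}\n")
        fh.write(f"passing_edges: {len(edges)}\n")
        fh.write(f"triplets: {len(triplets)}\n")
        summary = summarize_nodes(network)
        for rna_class in RNA_CLASSES:
            fh.write(f"nodes_{rna_class}: {summary[rna_class]}\n")
    return outdir
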