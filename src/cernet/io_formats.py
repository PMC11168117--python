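"""Readers and writers for the formats the pipeline touches.

Count tables are plain tab-separated files (first column = feature id,
remaining columns = samples); sample-to-condition assignments live in a
separate two-column file.  Transcript models come from GTF (1-based closed
intervals), sequences from FASTA, and the assembled network is exported both
as GraphML and as a Cytoscape-importable edge table.

The module also ships a small packaged fixture: the published table of 25
broodiness candidate genes with their associated miRNAs, lncRNAs and
circRNAs, used to build candidate-gene subnetworks.
"""

from __future__ import annotations

import csv
import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
import networkx as nx
import pandas as pd

RNA_CLASSES = ("mRNA", "miRNA", "lncRNA", "circRNA")

__all__ = [
    "RNA_CLASSES",
    "FormatError",
    "CountMatrix",
    "TranscriptModel",
    "AssociationRecord",
    "load_counts",
    "write_counts",
    "load_condition_map",
    "load_transcripts",
    "load_fasta",
    "write_fasta",
    "load_association_table",
    "association_fixture_path",
    "export_network",
]


class FormatError(ValueError):
    """Malformed input that the loaders refuse to coerce silently."""


@dataclass
class CountMatrix:
    """Non-negative integer expression of one RNA class over labeled samples.

    Parameters
    ----------
    counts
        Features x samples integer DataFrame; index = feature ids,
        columns = sample ids.
    rna_class
        One of ``mRNA``, ``miRNA``, ``lncRNA``, ``circRNA``.
    condition_of
        Mapping sample id -> condition label; exactly two conditions,
        each with at least two samples.
    """

    counts: pd.DataFrame
    rna_class: str
    condition_of: dict[str, str]

    def __post_init__(self) -> None:
        if self.rna_class not in RNA_CLASSES:
            raise FormatError(f"unknown rna_class {self.rna_class!r}")
        if self.counts.index.duplicated().any():
            dup = self.counts.index[self.counts.index.duplicated()][0]
            raise FormatError(f"duplicate feature id {dup!r}")
        if self.counts.columns.duplicated().any():
            dup = self.counts.columns[self.counts.columns.duplicated()][0]
            raise FormatError(f"duplicate sample id {dup!r}")
        missing = [s for s in self.counts.columns if s not in self.condition_of]
        if missing:
            raise FormatError(f"sample {missing[0]!r} missing from condition map")
        conditions = self.conditions
        if len(conditions) != 2:
            raise FormatError(f"expected exactly 2 conditions, got {sorted(conditions)}")
        for cond in conditions:
            n = sum(1 for s in self.counts.columns if self.condition_of[s] == cond)
            if n < 2:
                raise FormatError(f"condition {cond!r} has {n} sample(s); need >= 2")
        if (self.counts.values < 0).any():
            raise FormatError("negative counts")

    @property
    def feature_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def conditions(self) -> set[str]:
        return {self.condition_of[s] for s in self.counts.columns}

    def samples_in(self, condition: str) -> list[str]:
        return [s for s in self.counts.columns if self.condition_of[s] == condition]


@dataclass
class TranscriptModel:
    """A transcript as a strand-aware chain of 1-based closed exon intervals."""

    transcript_id: str
    gene_id: str
    chrom: str
    strand: str
    exons: list[tuple[int, int]]
    biotype: str = "protein_coding"

    def __post_init__(self) -> None:
        if self.strand not in {"+", "-"}:
            raise FormatError(f"{self.transcript_id}: bad strand {self.strand!r}")
        for start, end in self.exons:
            if end < start:
                raise FormatError(
                    f"{self.transcript_id}: exon end {end} < start {start}"
                )
        self.exons = sorted(self.exons)
        for (_, e1), (s2, _) in zip(self.exons, self.exons[1:]):
            if s2 <= e1:
                raise FormatError(f"{self.transcript_id}: overlapping exons")

    @property
    def span(self) -> tuple[int, int]:
        """Genomic span min(start)..max(end) over exons (1-based closed)."""
        return self.exons[0][0], self.exons[-1][1]

    @property
    def tss(self) -> int:
        """Transcription start site: span start on '+', span end on '-'."""
        return self.span[0] if self.strand == "+" else self.span[1]

    @property
    def introns(self) -> list[tuple[int, int]]:
        return [
            (e1 + 1, s2 - 1) for (_, e1), (s2, _) in zip(self.exons, self.exons[1:])
        ]


@dataclass
class AssociationRecord:
    """One candidate-gene row: an mRNA with its associated regulators."""

    gene: str
    pathway: str
    mirnas: list[str] = field(default_factory=list)
    lncrnas: list[str] = field(default_factory=list)
    circrnas: list[str] = field(default_factory=list)


# ---------------------------------------------------------------------------
# count tables


def load_condition_map(path: str | Path) -> dict[str, str]:
    """Read the two-column (sample, condition) tab-separated file."""
    mapping: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise FormatError(f"{path}:{lineno}: expected 2 columns")
            sample, condition = parts
            if sample in mapping:
                raise FormatError(f"{path}:{lineno}: duplicate sample {sample!r}")
            mapping[sample] = condition
    return mapping


def load_counts(
    path: str | Path, condition_map_path: str | Path, rna_class: str
) -> CountMatrix:
    """Load a tab-separated count table into a validated :class:`CountMatrix`.

    The header row carries sample ids; sample order follows the header.
    Duplicated ids, negative or non-integer counts, and samples absent from
    the condition map are format errors naming the offender.
    """
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    df.index = df.index.astype(str)
    if df.index.duplicated().any():
        dup = df.index[df.index.duplicated()][0]
        raise FormatError(f"{path}: duplicate feature id {dup!r}")
    try:
        numeric = df.astype("int64")
    except (ValueError, TypeError):
        for col in df.columns:
            for fid, value in df[col].items():
                if not re.fullmatch(r"[0-9]+", str(value).strip()):
                    raise FormatError(
                        f"{path}: non-integer count {value!r} at "
                        f"feature {fid!r}, sample {col!r}"
                    )
        raise  # pragma: no cover - unreachable
    condition_of = load_condition_map(condition_map_path)
    return CountMatrix(numeric, rna_class, condition_of)


def write_counts(matrix: CountMatrix, path: str | Path) -> None:
    matrix.counts.to_csv(path, sep="\t", index_label="feature_id")


# ---------------------------------------------------------------------------
# GTF

_GTF_ATTR = re.compile(r'(\w+) "([^"]*)"')


def load_transcripts(path_gtf: str | Path) -> list[TranscriptModel]:
    """Parse exon features of a GTF file into :class:`TranscriptModel` rows.

    Exons are grouped by ``transcript_id``, sorted, and validated.  The
    optional ``biotype`` attribute distinguishes protein-coding models from
    lncRNA candidates; rows without one default to ``protein_coding``.
    """
    exons: dict[str, TranscriptModel] = {}
    with open(path_gtf) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) != 9:
                raise FormatError(f"{path_gtf}:{lineno}: expected 9 columns")
            chrom, _source, feature, start, end, _score, strand, _frame, attrs = fields
            if feature != "exon":
                continue
            start_i, end_i = int(start), int(end)
            if end_i < start_i:
                raise FormatError(f"{path_gtf}:{lineno}: exon end < start")
            attr = dict(_GTF_ATTR.findall(attrs))
            try:
                tid, gid = attr["transcript_id"], attr["gene_id"]
            except KeyError as exc:
                raise FormatError(
                    f"{path_gtf}:{lineno}: missing {exc.args[0]} attribute"
                ) from None
            biotype = attr.get("biotype", "protein_coding")
            if tid in exons:
                exons[tid].exons.append((start_i, end_i))
            else:
                exons[tid] = TranscriptModel(
                    tid, gid, chrom, strand, [(start_i, end_i)], biotype
                )
    # re-validate after accumulating all exons
    return [
        TranscriptModel(t.transcript_id, t.gene_id, t.chrom, t.strand, t.exons, t.biotype)
        for t in exons.values()
    ]


# ---------------------------------------------------------------------------
# FASTA (thin wrappers so the rest of the package never touches Bio directly)


def load_fasta(path: str | Path) -> dict[str, str]:
    from Bio import SeqIO

    records = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in records:
            raise FormatError(f"{path}: duplicate sequence id {rec.id!r}")
        records[rec.id] = str(rec.seq).upper()
    return records


def write_fasta(sequences: dict[str, str], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# association table (candidate genes with their regulators)


def association_fixture_path() -> Path:
    """Path of the packaged 25-gene broodiness candidate table."""
    return Path(
        resources.files("cernet").joinpath("data/broodiness_candidate_genes.tsv")
    )


def _split_ids(cell: str) -> list[str]:
    # comma-separated lists; tolerate stray whitespace separators seen in
    # the published table (ids themselves never contain spaces)
    out = []
    for chunk in cell.split(","):
        out.extend(chunk.split())
    return out


def load_association_table(path: str | Path | None = None) -> list[AssociationRecord]:
    """Load the gene/pathway/miRNA/lncRNA/circRNA association table.

    With no argument, loads the packaged 25-gene broodiness fixture.
    """
    if path is None:
        path = association_fixture_path()
    with open(path) as fh:
        reader = csv.reader(fh, delimiter="\t")
        try:
            header = next(reader)
        except StopIteration:
            raise FormatError(f"{path}: empty file") from None
        if not header or header[0].strip().lower() != "gene":
            raise FormatError(f"{path}: missing gene column")
        records = []
        for row in reader:
            if not row or not any(cell.strip() for cell in row):
                continue
            row = list(row) + [""] * (5 - len(row))
            gene, pathway, mirnas, lncrnas, circrnas = (c.strip() for c in row[:5])
            if not gene:
                raise FormatError(f"{path}: row with empty gene symbol")
            records.append(
                AssociationRecord(
                    gene=gene,
                    pathway=pathway,
                    mirnas=_split_ids(mirnas),
                    lncrnas=_split_ids(lncrnas),
                    circrnas=_split_ids(circrnas),
                )
            )
    return records


# ---------------------------------------------------------------------------
# network export


def export_network(network, directory: str | Path) -> dict[str, Path]:
    """Write a network as a Cytoscape edge table and as GraphML.

    Returns the paths written.  Node attributes carried into GraphML:
    ``rna_class`` and ``de_direction``; edge attributes: ``kind`` plus any
    numeric annotations attached to the edge.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    edge_path = directory / "edges.tsv"
    graphml_path = directory / "network.graphml"

    attr_keys = sorted({k for _, _, _, attrs in network.edges for k in attrs})
    with open(edge_path, "w") as fh:
        fh.write("\t".join(["source", "interaction", "target", *attr_keys]) + "\n")
        for source, target, kind, attrs in network.edges:
            extra = [str(attrs.get(k, "")) for k in attr_keys]
            fh.write("\t".join([source, kind, target, *extra]) + "\n")

    graph = nx.DiGraph()
    for node_id, rna_class, de_direction in network.nodes:
        graph.add_node(node_id, rna_class=rna_class, de_direction=de_direction)
    for source, target, kind, attrs in network.edges:
        graph.add_edge(source, target, kind=kind, **attrs)
    nx.write_graphml(graph, graphml_path)
    return {"edges": edge_path, "graphml": graphml_path}
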