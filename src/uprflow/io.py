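"""Readers and writers for the pipeline's plain-text exchange formats.

Tables are TSV with headers, promoters travel as FASTA, the GO DAG as a
two-column (child, parent) TSV or an OBO file, and culture data as CSV
with empty cells for sparsely observed signals.
"""

from __future__ import annotations

import networkx as nx
import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .kinetics import CultureTimeSeries
from .motif import PromoterSet
from .summarize import ExpressionMatrix, ProbeIntensityMatrix

__all__ = [
    "read_probe_matrix",
    "write_probe_matrix",
    "read_design",
    "write_design",
    "read_expression",
    "write_expression",
    "read_promoters_fasta",
    "write_promoters_fasta",
    "read_genome_fasta",
    "read_gene_annotation_gff3",
    "read_go_graph",
    "write_go_graph",
    "read_annotations",
    "write_annotations",
    "read_culture_csv",
    "write_culture_csv",
    "read_gene_list",
    "write_gene_list",
]


def read_probe_matrix(matrix_path, map_path) -> ProbeIntensityMatrix:
    values = pd.read_csv(matrix_path, sep="\t", index_col=0).rename_axis(None)
    probe_map = pd.read_csv(map_path, sep="\t", index_col=0).iloc[:, 0]
    probe_map = probe_map.rename_axis(None).rename(None)
    return ProbeIntensityMatrix(values, probe_map)


def write_probe_matrix(m: ProbeIntensityMatrix, matrix_path, map_path) -> None:
    m.values.rename_axis("probe_id").to_csv(matrix_path, sep="\t")
    m.probe_to_probeset.rename("probeset_id").rename_axis("probe_id").to_csv(
        map_path, sep="\t"
    )


def read_design(path) -> pd.DataFrame:
    design = pd.read_csv(path, sep="\t")
    required = {"array_id", "condition", "replicate"}
    if not required <= set(design.columns):
        raise ValueError(f"design table must have columns {sorted(required)}")
    return design


def write_design(design: pd.DataFrame, path) -> None:
    design.to_csv(path, sep="\t", index=False)


def read_expression(path) -> ExpressionMatrix:
    return ExpressionMatrix(pd.read_csv(path, sep="\t", index_col=0).rename_axis(None))


def write_expression(expr: ExpressionMatrix, path) -> None:
    expr.values.rename_axis("probeset_id").to_csv(path, sep="\t")


def read_promoters_fasta(path) -> PromoterSet:
    sequences, full = {}, {}
    for rec in SeqIO.parse(str(path), "fasta"):
        sequences[rec.id] = str(rec.seq).upper()
        full[rec.id] = "partial" not in rec.description.split()
    return PromoterSet(sequences, full)


def write_promoters_fasta(promoters: PromoterSet, path) -> None:
    records = [
        SeqRecord(
            Seq(seq),
            id=gene,
            description="" if promoters.full_window.get(gene, True) else "partial",
        )
        for gene, seq in sorted(promoters.sequences.items())
    ]
    SeqIO.write(records, str(path), "fasta")


def read_genome_fasta(path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def read_gene_annotation_gff3(path, feature_type: str = "gene") -> pd.DataFrame:
    """Gene records (gene_id, contig, start, end, strand) from GFF3."""
    import gffutils

    db = gffutils.create_db(
        str(path), ":memory:", merge_strategy="create_unique", keep_order=True
    )
    rows = []
    for feat in db.features_of_type(feature_type):
        gene_id = feat.attributes.get("ID", [feat.id])[0]
        rows.append(
            {
                "gene_id": gene_id,
                "contig": feat.seqid,
                "start": feat.start,
                "end": feat.end,
                "strand": feat.strand,
            }
        )
    return pd.DataFrame(rows)


def read_go_graph(path) -> nx.DiGraph:
    """GO DAG from a (child, parent) TSV or an OBO file."""
    path = str(path)
    if path.endswith(".obo"):
        import obonet

        multi = obonet.read_obo(path)
        g = nx.DiGraph()
        g.add_nodes_from(multi.nodes)
        g.add_edges_from((u, v) for u, v, _ in multi.edges(keys=True))
        return g
    table = pd.read_csv(path, sep="\t")
    g = nx.DiGraph()
    for child, parent in table.itertuples(index=False):
        g.add_edge(str(child), str(parent))
    return g


def write_go_graph(g: nx.DiGraph, path) -> None:
    pd.DataFrame(sorted(g.edges), columns=["child", "parent"]).to_csv(
        path, sep="\t", index=False
    )


def read_annotations(path) -> dict[str, set[str]]:
    table = pd.read_csv(path, sep="\t")
    direct: dict[str, set[str]] = {}
    for gene, term in table.itertuples(index=False):
        direct.setdefault(str(gene), set()).add(str(term))
    return direct


def write_annotations(direct: dict[str, set[str]], path) -> None:
    rows = [(g, t) for g in sorted(direct) for t in sorted(direct[g])]
    pd.DataFrame(rows, columns=["gene", "term"]).to_csv(path, sep="\t", index=False)


def read_culture_csv(path) -> CultureTimeSeries:
    return CultureTimeSeries(pd.read_csv(path))


def write_culture_csv(ts: CultureTimeSeries, path) -> None:
    ts.data.to_csv(path, index=False)


def read_gene_list(path) -> set[str]:
    with open(path) as fh:
        return {line.strip() for line in fh if line.strip()}


def write_gene_list(genes: set[str], path) -> None:
    with open(path, "w") as fh:
        for gene in sorted(genes):
            fh.write(gene + "\n")
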