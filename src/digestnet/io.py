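"""Readers and writers for the delimited-text formats the pipeline uses.

Tables are tab-separated UTF-8 with ``#`` comment lines and the id in the
first column; dates are ISO-8601; missing values are empty fields or "NA".
Sequences are FASTA (via Biopython); networks are exported as an edge-list
TSV or GraphML.
"""

from __future__ import annotations

import datetime as _dt
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .datatypes import (
    NODE_ATTRS,
    RANKS,
    AbundanceTable,
    ParameterSeries,
    TaxonomyTable,
    ValidationError,
)

__all__ = [
    "read_tsv",
    "read_abundance_table",
    "write_abundance_table",
    "read_taxonomy",
    "write_taxonomy",
    "read_parameter_series",
    "write_parameter_series",
    "read_fasta",
    "write_fasta",
    "write_network",
    "read_network",
    "write_mag_records",
    "read_mag_records",
    "write_expression",
    "read_expression",
]

_NA = ("", "NA")


def read_tsv(path, **kwargs) -> pd.DataFrame:
    """Read a TSV with '#' comments and the first column as index."""
    return pd.read_csv(
        path, sep="\t", comment="#", index_col=0,
        na_values=list(_NA), keep_default_na=False, **kwargs,
    )


# -- abundance tables ----------------------------------------------------

def read_abundance_table(path, metadata_path) -> AbundanceTable:
    """Read an ASV count table plus its sample metadata.

    ``path``: TSV with ASV ids in the first column and sample ids in the
    header.  ``metadata_path``: TSV with sample ids in the first column and
    ``date`` / ``configuration`` columns.  Metadata row order is irrelevant.
    """
    counts = read_tsv(path)
    if counts.isna().to_numpy().any():
        rows = counts.index[counts.isna().any(axis=1)].tolist()
        raise ValidationError(f"missing counts for ASVs {rows} in {path}")
    try:
        counts = counts.astype(float)
    except ValueError as exc:
        raise ValidationError(f"non-numeric count in {path}: {exc}") from None
    meta = read_tsv(metadata_path)
    for col in ("date", "configuration"):
        if col not in meta.columns:
            raise ValidationError(f"metadata lacks a {col!r} column")
    unknown = [s for s in meta.index if s not in counts.columns]
    if unknown:
        raise ValidationError(f"metadata samples not in count table: {unknown}")
    table = AbundanceTable(
        counts.astype(int) if (counts == counts.round()).all().all() else counts,
        meta["date"],
        meta["configuration"],
    )
    return table


def write_abundance_table(table: AbundanceTable, path, metadata_path) -> None:
    df = table.counts.copy()
    df.index.name = "asv_id"
    df.to_csv(path, sep="\t")
    meta = pd.DataFrame(
        {
            "date": [d.isoformat() for d in table.sample_dates],
            "configuration": table.configuration.to_numpy(),
        },
        index=pd.Index(table.sample_ids, name="sample_id"),
    )
    meta.to_csv(metadata_path, sep="\t")


# -- taxonomy ------------------------------------------------------------

def read_taxonomy(path) -> TaxonomyTable:
    frame = read_tsv(path, dtype=str)
    return TaxonomyTable(frame)


def write_taxonomy(tax: TaxonomyTable, path) -> None:
    df = tax.frame.copy()
    df.index.name = "id"
    df.to_csv(path, sep="\t", na_rep="NA")


# -- physicochemical series ---------------------------------------------

def read_parameter_series(path) -> ParameterSeries:
    frame = read_tsv(path)
    return ParameterSeries(frame)


def write_parameter_series(series: ParameterSeries, path) -> None:
    df = series.values.copy()
    df.index = [d.isoformat() for d in df.index]
    df.index.name = "date"
    df.to_csv(path, sep="\t", na_rep="NA")


# -- FASTA ---------------------------------------------------------------

def read_fasta(path) -> dict[str, str]:
    """FASTA -> {id: upper-cased sequence}; duplicate ids and empty records
    are errors."""
    out: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in out:
            raise ValidationError(f"duplicate FASTA id {rec.id!r} in {path}")
        seq = str(rec.seq).upper()
        if not seq:
            raise ValidationError(f"empty sequence for {rec.id!r} in {path}")
        out[rec.id] = seq
    return out


def write_fasta(seqs: dict[str, str], path) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in seqs.items()]
    SeqIO.write(records, str(path), "fasta")


# -- networks ------------------------------------------------------------

def write_network(net: nx.Graph, path, format: str = "edge_tsv") -> None:
    """Export a co-occurrence network.

    ``edge_tsv`` writes one row per edge with weight and BH-adjusted p;
    ``graphml`` preserves all node and edge attributes (None attributes are
    omitted, GraphML cannot encode them).
    """
    if format == "edge_tsv":
        rows = [
            {"source": u, "target": v,
             "weight": d.get("weight", np.nan),
             "qvalue": d.get("qvalue", np.nan)}
            for u, v, d in net.edges(data=True)
        ]
        pd.DataFrame(rows, columns=["source", "target", "weight", "qvalue"]).to_csv(
            path, sep="\t", index=False
        )
    elif format == "graphml":
        clean = nx.Graph()
        for n, data in net.nodes(data=True):
            clean.add_node(n, **{k: v for k, v in data.items() if v is not None})
        for u, v, data in net.edges(data=True):
            clean.add_edge(u, v, **{k: v for k, v in data.items() if v is not None})
        nx.write_graphml(clean, str(path))
    else:
        raise ValueError(f"unknown network format {format!r}")


def read_network(path, format: str = "edge_tsv") -> nx.Graph:
    if format == "edge_tsv":
        df = pd.read_csv(path, sep="\t")
        net = nx.Graph()
        for row in df.itertuples(index=False):
            net.add_edge(row.source, row.target, weight=row.weight, qvalue=row.qvalue)
        return net
    if format == "graphml":
        return nx.read_graphml(str(path))
    raise ValueError(f"unknown network format {format!r}")


# -- MAG records ---------------------------------------------------------

def write_mag_records(mags, directory) -> None:
    """Write a MAG collection as three text files under ``directory``:

    ``mags.tsv`` (metrics + semicolon-joined taxonomy), ``mag_16s.fasta``
    (ids ``<mag_id>|<k>``), and ``mag_genes.tsv`` (gene id, length,
    comma-joined annotation labels).
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    rows, seqs, gene_rows = [], {}, []
    for mag in mags:
        rows.append(
            {"mag_id": mag.mag_id,
             "taxonomy": ";".join(mag.taxonomy),
             "completeness": mag.completeness,
             "contamination": mag.contamination,
             "rrna_5S": mag.rrna_counts.get("5S", 0),
             "rrna_16S": mag.rrna_counts.get("16S", 0),
             "rrna_23S": mag.rrna_counts.get("23S", 0)}
        )
        for k, ssu in enumerate(mag.ssu_sequences):
            seqs[f"{mag.mag_id}|{k}"] = ssu
        for gene in mag.genes:
            gene_rows.append(
                {"gene_id": gene.gene_id, "mag_id": mag.mag_id,
                 "length": gene.length, "labels": ",".join(gene.labels)}
            )
    pd.DataFrame(rows).set_index("mag_id").to_csv(directory / "mags.tsv", sep="\t")
    write_fasta(seqs, directory / "mag_16s.fasta")
    pd.DataFrame(gene_rows).set_index("gene_id").to_csv(
        directory / "mag_genes.tsv", sep="\t"
    )


def read_mag_records(directory):
    from .datatypes import Gene, MagRecord

    directory = Path(directory)
    meta = read_tsv(directory / "mags.tsv", dtype={"taxonomy": str})
    seqs = read_fasta(directory / "mag_16s.fasta")
    genes = read_tsv(directory / "mag_genes.tsv", dtype={"labels": str})
    mags = []
    for mag_id, row in meta.iterrows():
        tax = row["taxonomy"]
        lineage = [t for t in str(tax).split(";") if t] if pd.notna(tax) else []
        ssu = [seqs[k] for k in sorted(seqs) if k.startswith(f"{mag_id}|")]
        sub = genes[genes["mag_id"] == mag_id]
        gene_list = [
            Gene(gid, int(g["length"]),
                 tuple(str(g["labels"]).split(",")) if pd.notna(g["labels"]) else ())
            for gid, g in sub.iterrows()
        ]
        mags.append(
            MagRecord(
                mag_id=str(mag_id), taxonomy=lineage,
                completeness=float(row["completeness"]),
                contamination=float(row["contamination"]),
                rrna_counts={"5S": int(row["rrna_5S"]),
                             "16S": int(row["rrna_16S"]),
                             "23S": int(row["rrna_23S"])},
                ssu_sequences=ssu, genes=gene_list,
            )
        )
    return mags


# -- expression ----------------------------------------------------------

def write_expression(expr, prefix) -> None:
    """Write an ExpressionTable as ``<prefix>_genes.tsv`` + ``<prefix>_counts.tsv``."""
    prefix = str(prefix)
    info = expr.gene_info.copy()
    info.index.name = "gene_id"
    info.to_csv(f"{prefix}_genes.tsv", sep="\t")
    counts = expr.counts.copy()
    counts.index.name = "gene_id"
    counts.to_csv(f"{prefix}_counts.tsv", sep="\t")


def read_expression(prefix):
    from .datatypes import ExpressionTable

    prefix = str(prefix)
    info = read_tsv(f"{prefix}_genes.tsv", dtype={"mag_id": str})
    counts = read_tsv(f"{prefix}_counts.tsv")
    return ExpressionTable(info, counts)
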