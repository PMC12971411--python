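"""Readers and writers for the standard formats the pipeline consumes.

FASTA goes through Biopython, GFF3 through gffutils (in-memory db), VCF
through pysam (see :mod:`panfam.sv`); the simple tabular dialects
(OrthoFinder ``Orthogroups.tsv``, HMMER domtblout, BLAST outfmt 6) are
parsed here with pandas/plain splitting since they are whitespace/tab
tables, not structured formats.
"""

from __future__ import annotations

import os
from pathlib import Path

import gffutils
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord


class ParseError(ValueError):
    """Malformed input row; message names the file and line number."""


# ---------------------------------------------------------------- FASTA


def read_fasta(path) -> dict[str, str]:
    """Read a FASTA file into an ordered {id: sequence} mapping."""
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(path, records: dict[str, str], descriptions: dict[str, str] | None = None) -> None:
    descriptions = descriptions or {}
    recs = [
        SeqRecord(Seq(seq), id=name, description=descriptions.get(name, ""))
        for name, seq in records.items()
    ]
    SeqIO.write(recs, str(path), "fasta")


# ---------------------------------------------------------------- GFF3

GENE_COLUMNS = ["gene_id", "genome", "chrom", "start", "end", "strand"]


def read_gff3_genes(path, genome: str | None = None) -> pd.DataFrame:
    """Extract gene features from a GFF3 file.

    Returns a DataFrame with columns gene_id, genome, chrom, start, end,
    strand (1-based inclusive coordinates). `genome` defaults to the file
    stem.
    """
    path = Path(path)
    genome = genome if genome is not None else path.stem.removesuffix(".gff3")
    db = gffutils.create_db(
        str(path),
        dbfn=":memory:",
        merge_strategy="create_unique",
        keep_order=True,
    )
    rows = [
        (feat.id, genome, feat.seqid, feat.start, feat.end, feat.strand)
        for feat in db.features_of_type("gene")
    ]
    return pd.DataFrame(rows, columns=GENE_COLUMNS)


def write_gff3(path, genes: pd.DataFrame) -> None:
    """Write gene rows (columns as in GENE_COLUMNS) as a minimal GFF3."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        ordered = genes.sort_values(["chrom", "start", "gene_id"])
        for row in ordered.itertuples():
            fh.write(
                f"{row.chrom}\tpanfam\tgene\t{row.start}\t{row.end}\t.\t"
                f"{row.strand}\t.\tID={row.gene_id}\n"
            )


# ------------------------------------------------ OrthoFinder table


def read_orthogroups(path) -> pd.DataFrame:
    """Read an OrthoFinder-style ``Orthogroups.tsv``.

    First column is the orthogroup id; remaining columns are genomes with
    comma-separated gene lists. Returns a long DataFrame
    (og, genome, gene_id).
    """
    wide = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    rows = []
    for row in wide.itertuples(index=False):
        og = row[0]
        for genome, cell in zip(wide.columns[1:], row[1:]):
            for gene in str(cell).split(","):
                gene = gene.strip()
                if gene:
                    rows.append((og, genome, gene))
    return pd.DataFrame(rows, columns=["og", "genome", "gene_id"])


def write_orthogroups(path, membership: pd.DataFrame, genomes: list[str] | None = None) -> None:
    """Write a long (og, genome, gene_id) table as ``Orthogroups.tsv``."""
    if genomes is None:
        genomes = sorted(membership["genome"].unique())
    ogs = sorted(membership["og"].unique())
    grouped = membership.groupby(["og", "genome"])["gene_id"].apply(
        lambda s: ", ".join(sorted(s))
    )
    with open(path, "w") as fh:
        fh.write("Orthogroup\t" + "\t".join(genomes) + "\n")
        for og in ogs:
            cells = [grouped.get((og, g), "") for g in genomes]
            fh.write(og + "\t" + "\t".join(cells) + "\n")


# ------------------------------------------------ HMMER domtblout

DOMTBL_COLUMNS = ["gene_id", "domain_acc", "evalue", "env_from", "env_to"]


def read_domtbl(path) -> pd.DataFrame:
    """Read a HMMER domtblout-style whitespace table.

    Keeps target name (gene), query accession (domain), the per-domain
    independent E-value and the envelope coordinates on the protein.
    """
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split()
            if len(fields) < 21:
                raise ParseError(f"{path}: line {lineno}: expected >=21 fields, got {len(fields)}")
            try:
                rows.append(
                    (
                        fields[0],
                        fields[4],
                        float(fields[12]),
                        int(fields[19]),
                        int(fields[20]),
                    )
                )
            except ValueError as exc:
                raise ParseError(f"{path}: line {lineno}: {exc}") from exc
    return pd.DataFrame(rows, columns=DOMTBL_COLUMNS)


def write_domtbl(path, hits: pd.DataFrame) -> None:
    """Write hits (columns as DOMTBL_COLUMNS) in a domtblout-shaped layout."""
    with open(path, "w") as fh:
        fh.write("# target qacc ievalue envfrom envto (domtblout-style)\n")
        for row in hits.itertuples():
            plen = max(row.env_to + 5, 100)
            fh.write(
                f"{row.gene_id} - {plen} UDPGT {row.domain_acc} 360 "
                f"{row.evalue:g} 100.0 0.1 1 1 {row.evalue:g} {row.evalue:g} 99.0 0.1 "
                f"1 360 {row.env_from} {row.env_to} {row.env_from} {row.env_to} 0.95 -\n"
            )


# ------------------------------------------------ BLAST outfmt 6

BLAST6_COLUMNS = [
    "query", "subject", "pident", "length", "mismatch", "gapopen",
    "qstart", "qend", "sstart", "send", "evalue", "bitscore",
]


def read_blast_tab(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", names=BLAST6_COLUMNS, comment="#")


def write_blast_tab(path, hits: pd.DataFrame) -> None:
    hits[BLAST6_COLUMNS].to_csv(path, sep="\t", header=False, index=False)


# ------------------------------------------------ generic tables


def read_tsv(path, **kwargs) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", **kwargs)


def write_tsv(path, frame: pd.DataFrame, index: bool = False) -> None:
    os.makedirs(Path(path).parent, exist_ok=True)
    frame.to_csv(path, sep="\t", index=index)
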