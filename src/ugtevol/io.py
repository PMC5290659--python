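"""FASTA / GFF3 / TSV input and output shared by all pipeline stages."""

from __future__ import annotations

import csv
from pathlib import Path

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .sequence import CodingGene, ProteinRecord

__all__ = [
    "read_fasta",
    "write_fasta",
    "read_coding_genes",
    "read_chromosome_table",
    "read_gff3_exons",
    "write_tsv",
]


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a FASTA file into an ordered {id: sequence} mapping."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(path: str | Path, records: dict[str, str]) -> None:
    """Write sequences as multi-line FASTA, wrapped at 60 columns."""
    seqs = [SeqRecord(Seq(s), id=name, description="") for name, s in records.items()]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=60)
        writer.write_file(seqs)


def read_chromosome_table(path: str | Path) -> dict[str, str]:
    """Read a two-column TSV (gene id, chromosome label), header optional."""
    out: dict[str, str] = {}
    with open(path) as fh:
        for i, row in enumerate(csv.reader(fh, delimiter="\t")):
            if not row or row[0].startswith("#"):
                continue
            if i == 0 and row[0].lower() in ("id", "gene", "gene_id"):
                continue
            out[row[0]] = row[1]
    return out


def read_gff3_exons(path: str | Path) -> dict[str, tuple[str, list[tuple[int, int]]]]:
    """Extract per-gene (seqid, exon spans) from a GFF3 file.

    Exon features are grouped by their ``Parent`` (falling back to ``ID``)
    attribute; spans are returned 1-based inclusive, sorted by start, and
    the seqid column is used as the chromosome label.
    """
    import gffutils

    db = gffutils.create_db(
        str(path), ":memory:", force=True, keep_order=True,
        merge_strategy="create_unique",
    )
    genes: dict[str, tuple[str, list[tuple[int, int]]]] = {}
    for exon in db.features_of_type("exon"):
        parents = exon.attributes.get("Parent") or exon.attributes.get("ID") or ["?"]
        for parent in parents:
            chrom, spans = genes.setdefault(parent, (exon.seqid, []))
            spans.append((exon.start, exon.end))
    return {g: (c, sorted(s)) for g, (c, s) in genes.items()}


def read_coding_genes(
    cds_fasta: str | Path,
    chromosome_table: str | Path | None = None,
    genomic_fasta: str | Path | None = None,
    gff3: str | Path | None = None,
) -> list[CodingGene]:
    """Assemble :class:`CodingGene` objects from FASTA plus optional metadata.

    Chromosome labels come from the TSV table if given, otherwise from the
    GFF3 seqid; exon spans come from the GFF3 and are validated against the
    CDS when the genomic sequence is also available.
    """
    cds = read_fasta(cds_fasta)
    chroms = read_chromosome_table(chromosome_table) if chromosome_table else {}
    genomic = read_fasta(genomic_fasta) if genomic_fasta else {}
    gff = read_gff3_exons(gff3) if gff3 else {}

    genes = []
    for gid, seq in cds.items():
        chrom, spans = gff.get(gid, (None, None))
        genes.append(
            CodingGene(
                id=gid,
                cds=seq,
                chromosome=chroms.get(gid, chrom),
                genomic=genomic.get(gid),
                exon_spans=spans if (spans and gid in genomic) else None,
            )
        )
    return genes


def write_tsv(path: str | Path, rows: list[dict], columns: list[str] | None = None) -> None:
    """Write a list of dict rows as TSV with a fixed column order."""
    if columns is None:
        columns = list(rows[0]) if rows else []
    with open(path, "w", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=columns, delimiter="\t")
        writer.writeheader()
        for row in rows:
            writer.writerow({c: row.get(c, "") for c in columns})


def proteins_of(genes: list[CodingGene]) -> list[ProteinRecord]:
    return [g.protein_record() for g in genes]
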