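"""Core sequence domain types: coding genes, protein records, translation.

A :class:`CodingGene` is the unit that flows through the whole pipeline:
a CDS (length divisible by 3), its derived protein, and optionally the
genomic sequence it was spliced from, its exon spans and a chromosome
label. All coordinates in this package are 1-based inclusive.
"""

from __future__ import annotations

import statistics
from dataclasses import dataclass, field

from Bio.Data import CodonTable
from Bio.SeqUtils import molecular_weight

__all__ = [
    "CodingGene",
    "ProteinRecord",
    "translate_cds",
    "protein_mass",
    "length_filter",
    "STANDARD_TABLE",
]

STANDARD_TABLE = CodonTable.unambiguous_dna_by_id[1]

_DNA = set("ACGT")


class InternalStopError(ValueError):
    """An in-frame stop codon occurs before the final codon."""


def translate_cds(
    cds: str,
    table: CodonTable.CodonTable = STANDARD_TABLE,
    on_internal_stop: str = "error",
) -> str:
    """Translate a coding sequence to protein, dropping a terminal stop.

    Parameters
    ----------
    cds
        DNA over A/C/G/T with length divisible by 3.
    table
        Genetic code (defaults to the standard code, NCBI table 1).
    on_internal_stop
        ``"error"`` (default) raises :class:`InternalStopError` on an
        in-frame stop before the last codon; ``"truncate"`` returns the
        residues preceding the first stop.
    """
    cds = cds.upper()
    if len(cds) % 3 != 0:
        raise ValueError(f"CDS length {len(cds)} is not divisible by 3")
    bad = set(cds) - _DNA
    if bad:
        raise ValueError(f"non-ACGT characters in CDS: {sorted(bad)}")
    if on_internal_stop not in ("error", "truncate"):
        raise ValueError(f"unknown internal-stop mode {on_internal_stop!r}")

    stops = set(table.stop_codons)
    fwd = table.forward_table
    residues = []
    n_codons = len(cds) // 3
    for i in range(n_codons):
        codon = cds[3 * i : 3 * i + 3]
        if codon in stops:
            if i == n_codons - 1:
                break  # terminal stop dropped
            if on_internal_stop == "truncate":
                break
            raise InternalStopError(f"internal stop codon {codon} at codon {i + 1}")
        residues.append(fwd[codon])
    return "".join(residues)


def protein_mass(sequence: str) -> float:
    """Average molecular mass of a protein chain in daltons.

    Sum of average residue masses plus one water (the mass of the free
    polypeptide); an empty chain returns the mass of water. Average, not
    monoisotopic, masses: the convention behind SDS-PAGE-style kDa values.
    """
    return molecular_weight(sequence.upper(), seq_type="protein")


@dataclass
class ProteinRecord:
    """A protein sequence with its derived average molecular mass."""

    id: str
    sequence: str
    mass_da: float = field(init=False)

    def __post_init__(self) -> None:
        self.mass_da = protein_mass(self.sequence)

    @property
    def mass_kda(self) -> float:
        return self.mass_da / 1000.0

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class CodingGene:
    """A coding gene: CDS, derived protein, optional genomic context.

    ``exon_spans`` are 1-based inclusive coordinates on ``genomic``; when
    given, the concatenated exon sequence must equal the CDS.
    """

    id: str
    cds: str
    chromosome: str | None = None
    genomic: str | None = None
    exon_spans: list[tuple[int, int]] | None = None
    protein: str = field(init=False)

    def __post_init__(self) -> None:
        self.cds = self.cds.upper()
        self.protein = translate_cds(self.cds)
        if self.exon_spans is not None:
            if self.genomic is None:
                raise ValueError(f"{self.id}: exon_spans given without genomic")
            joined = "".join(
                self.genomic[s - 1 : e].upper() for s, e in self.exon_spans
            )
            if joined != self.cds:
                raise ValueError(f"{self.id}: concatenated exons do not equal the CDS")

    @property
    def n_codons(self) -> int:
        return len(self.cds) // 3

    def protein_record(self) -> ProteinRecord:
        return ProteinRecord(self.id, self.protein)


def length_filter(
    proteins: list[ProteinRecord], min_fraction: float = 0.5
) -> tuple[list[ProteinRecord], list[ProteinRecord]]:
    """Partition proteins into (kept, excluded) by fractional-median length.

    Sequences strictly shorter than ``min_fraction`` x the median length
    are excluded — the rule used to drop probable truncated gene models
    before tree building. The rule is applied to a fixed point (dropping
    short sequences can raise the median; iterating makes the partition
    idempotent on its kept set). The partition is exhaustive and disjoint.
    """
    if not proteins:
        raise ValueError("length_filter requires at least one protein")
    if not 0 < min_fraction <= 1:
        raise ValueError(f"min_fraction must be in (0, 1], got {min_fraction}")
    kept = list(proteins)
    excluded: list[ProteinRecord] = []
    while True:
        cutoff = min_fraction * statistics.median(len(p) for p in kept)
        dropped = [p for p in kept if len(p) < cutoff]
        if not dropped:
            return kept, excluded
        kept = [p for p in kept if len(p) >= cutoff]
        excluded.extend(dropped)
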