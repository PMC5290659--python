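"""In-silico overlap-extension PCR: intron removal and chimeric primers.

Given a genomic fragment with a single known intron, the two exons are
fused into a CDS and four primers are designed: external forward/reverse
primers from the CDS ends, and two 30-nt internal chimeric primers that
straddle the exon-exon junction (15 nt from the end of exon I joined to
15 nt from the start of exon II; the reverse internal primer is the
reverse complement of the forward one).
"""

from __future__ import annotations

from dataclasses import dataclass

from Bio.Seq import Seq

__all__ = ["SplicePlan", "splice", "design_splice_primers", "insert_intron"]

JUNCTION_ARM = 15  # nt on each side of the exon-exon junction
EXTERNAL_PRIMER_LEN = 20


def _check_span(genomic: str, intron_span: tuple[int, int]) -> tuple[int, int]:
    start, end = intron_span
    if not 1 <= start <= end <= len(genomic):
        raise ValueError(f"intron span {intron_span} outside sequence of length {len(genomic)}")
    if start == 1 or end == len(genomic):
        raise ValueError("intron at a sequence boundary leaves an empty exon")
    return start, end


def splice(genomic: str, intron_span: tuple[int, int]) -> str:
    """Remove the intron: fused CDS = exon I + exon II.

    ``intron_span`` is 1-based inclusive on the genomic sequence; the
    fused length is len(genomic) minus the intron length.
    """
    genomic = genomic.upper()
    start, end = _check_span(genomic, intron_span)
    return genomic[: start - 1] + genomic[end:]


def insert_intron(cds: str, intron: str, after: int) -> str:
    """Inverse of :func:`splice`: insert an intron after CDS position ``after``."""
    if not 1 <= after < len(cds):
        raise ValueError(f"insertion point {after} not strictly inside the CDS")
    if not intron:
        raise ValueError("zero-length intron")
    return cds[:after] + intron + cds[after:]


@dataclass
class SplicePlan:
    """Primer design for splicing one single-intron gene."""

    gene_id: str
    genomic: str
    intron_span: tuple[int, int]
    exon1: str
    exon2: str
    fused: str
    primers: dict[str, str]

    def primer_rows(self) -> list[dict]:
        """TSV-ready primer report rows."""
        return [
            {"gene": self.gene_id, "name": name, "sequence": seq, "length": len(seq)}
            for name, seq in self.primers.items()
        ]


def design_splice_primers(
    genomic: str,
    intron_span: tuple[int, int],
    gene_id: str = "gene",
    external_len: int = EXTERNAL_PRIMER_LEN,
) -> SplicePlan:
    """Design the four overlap-extension primers for a single-intron gene.

    exonII_F = last 15 nt of exon I + first 15 nt of exon II (sense);
    exonI_R = reverse complement of exonII_F; the external primers are the
    first/last ``external_len`` nt of the fused CDS (reverse primer on the
    antisense strand). Each exon must be at least 15 nt.
    """
    genomic = genomic.upper()
    start, end = _check_span(genomic, intron_span)
    exon1 = genomic[: start - 1]
    exon2 = genomic[end:]
    if len(exon1) < JUNCTION_ARM or len(exon2) < JUNCTION_ARM:
        raise ValueError(f"each exon must be >= {JUNCTION_ARM} nt for junction primers")
    fused = exon1 + exon2

    exonII_F = exon1[-JUNCTION_ARM:] + exon2[:JUNCTION_ARM]
    primers = {
        "exonic_fwd": fused[:external_len],
        "exonic_rev": str(Seq(fused[-external_len:]).reverse_complement()),
        "exonI_R": str(Seq(exonII_F).reverse_complement()),
        "exonII_F": exonII_F,
    }
    return SplicePlan(gene_id, genomic, (start, end), exon1, exon2, fused, primers)
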