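"""Global protein alignment and projection to paired codons.

Pairwise affine-gap Needleman-Wunsch (via Biopython's C PairwiseAligner)
stands in for the progressive aligners typically used upstream of Ka/Ks:
the codon-counting step is strictly pairwise, so pairwise alignments with
pairwise gap deletion are what the estimator actually consumes.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from pathlib import Path

from Bio import Align
from Bio.Align import substitution_matrices

from .sequence import STANDARD_TABLE, translate_cds

__all__ = [
    "ProteinAlignment",
    "CodonPairAlignment",
    "global_align",
    "project_to_codons",
    "load_matrix",
]

DEFAULT_MATRIX = "BLOSUM62"
DEFAULT_GAP_OPEN = -11.0
DEFAULT_GAP_EXTEND = -1.0


@dataclass
class ProteinAlignment:
    """A global pairwise protein alignment with score and identity."""

    id_a: str
    id_b: str
    aligned_a: str
    aligned_b: str
    score: float

    def __post_init__(self) -> None:
        if len(self.aligned_a) != len(self.aligned_b):
            raise ValueError("aligned sequences differ in length")
        if any(x == "-" and y == "-" for x, y in zip(self.aligned_a, self.aligned_b)):
            raise ValueError("gap/gap column in alignment")

    @property
    def identity(self) -> float:
        """Fraction of identical residues over columns with no gap."""
        shared = [
            (x, y)
            for x, y in zip(self.aligned_a, self.aligned_b)
            if x != "-" and y != "-"
        ]
        if not shared:
            return 0.0
        return sum(x == y for x, y in shared) / len(shared)

    @property
    def n_columns(self) -> int:
        return len(self.aligned_a)


@dataclass
class CodonPairAlignment:
    """Gap-free paired codon columns for two genes — the NG86 input."""

    id_a: str
    id_b: str
    codons_a: list[str]
    codons_b: list[str]

    def __post_init__(self) -> None:
        if len(self.codons_a) != len(self.codons_b):
            raise ValueError("codon lists differ in length")

    @property
    def n_codons(self) -> int:
        return len(self.codons_a)


@lru_cache(maxsize=8)
def load_matrix(name_or_path: str = DEFAULT_MATRIX):
    """Load a substitution matrix by name or from an NCBI-format file."""
    if Path(name_or_path).is_file():
        return substitution_matrices.read(name_or_path)
    return substitution_matrices.load(name_or_path)


def _aligner(matrix, gap_open: float, gap_extend: float) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = matrix
    aligner.open_gap_score = gap_open
    aligner.extend_gap_score = gap_extend
    return aligner


def global_align(
    a: str,
    b: str,
    id_a: str = "a",
    id_b: str = "b",
    matrix: str = DEFAULT_MATRIX,
    gap_open: float = DEFAULT_GAP_OPEN,
    gap_extend: float = DEFAULT_GAP_EXTEND,
) -> ProteinAlignment:
    """Optimal global alignment under affine gap penalties.

    The traceback is deterministic: among co-optimal alignments the
    aligner's canonical first traceback is returned, so repeated runs and
    reversed-argument runs are reproducible.
    """
    if not a or not b:
        raise ValueError("cannot align an empty sequence")
    aligner = _aligner(load_matrix(matrix), gap_open, gap_extend)
    aln = aligner.align(a, b)[0]
    return ProteinAlignment(id_a, id_b, str(aln[0]), str(aln[1]), aln.score)


def align_score(a: str, b: str, **kwargs) -> float:
    """Alignment score only (skips traceback; used by all-vs-all scans)."""
    if not a or not b:
        raise ValueError("cannot align an empty sequence")
    matrix = kwargs.pop("matrix", DEFAULT_MATRIX)
    gap_open = kwargs.pop("gap_open", DEFAULT_GAP_OPEN)
    gap_extend = kwargs.pop("gap_extend", DEFAULT_GAP_EXTEND)
    return _aligner(load_matrix(matrix), gap_open, gap_extend).score(a, b)


def project_to_codons(
    aln: ProteinAlignment, cds_a: str, cds_b: str
) -> CodonPairAlignment:
    """Map a protein alignment back to paired codons.

    Columns with a gap in either sequence are dropped (pairwise deletion),
    as are columns where either source codon is a stop — the output never
    contains a gap or stop codon.
    """
    stops = set(STANDARD_TABLE.stop_codons)
    cds_a, cds_b = cds_a.upper(), cds_b.upper()
    for label, cds, aligned in (("a", cds_a, aln.aligned_a), ("b", cds_b, aln.aligned_b)):
        if translate_cds(cds) != aligned.replace("-", ""):
            raise ValueError(f"CDS {label} does not translate to its aligned protein")

    codons_a: list[str] = []
    codons_b: list[str] = []
    ia = ib = 0
    for x, y in zip(aln.aligned_a, aln.aligned_b):
        if x != "-" and y != "-":
            ca = cds_a[3 * ia : 3 * ia + 3]
            cb = cds_b[3 * ib : 3 * ib + 3]
            if ca not in stops and cb not in stops:
                codons_a.append(ca)
                codons_b.append(cb)
        if x != "-":
            ia += 1
        if y != "-":
            ib += 1
    return CodonPairAlignment(aln.id_a, aln.id_b, codons_a, codons_b)
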