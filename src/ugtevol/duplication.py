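"""Duplicate-gene detection: all-vs-all similarity and reciprocal best hits.

Two genes are declared duplicate copies when each is the other's
top-scoring partner in an all-vs-all protein similarity scan (reciprocal
best hits, RBH), with pairs below a chance-similarity score threshold
discarded up front. Pairs are then classified as intra- or
inter-chromosomal from a (possibly partial) chromosome assignment.
"""

from __future__ import annotations

import random
import statistics
from dataclasses import dataclass

from .align import align_score
from .sequence import CodingGene

__all__ = [
    "DuplicationPair",
    "all_vs_all",
    "reciprocal_best_hits",
    "classify_pairs",
    "calibrate_score_threshold",
]

ScoreTable = dict[tuple[str, str], float]


@dataclass
class DuplicationPair:
    """A called duplicate pair in canonical (id_a < id_b) order."""

    id_a: str
    id_b: str
    score: float
    chromosome_a: str | None = None
    chromosome_b: str | None = None
    kind: str = "unplaced"  # intra_chromosomal | inter_chromosomal | unplaced


def calibrate_score_threshold(
    proteins: dict[str, str],
    n_shuffles: int = 200,
    n_sigma: float = 6.0,
    seed: int = 0,
    **align_kwargs,
) -> float:
    """Score threshold excluding chance similarity, by permutation.

    Residue-shuffled sequence pairs destroy homology while preserving
    length and composition; the threshold mean + ``n_sigma``·SD of their
    alignment scores puts the chance-pass probability far below 1e-6 under
    a Gaussian tail (6 SD ~ 1e-9). This mirrors the intent of a stringent
    BLAST E-value cutoff without Karlin-Altschul statistics.
    """
    rng = random.Random(seed)
    seqs = list(proteins.values())
    if len(seqs) < 2:
        raise ValueError("need at least 2 proteins to calibrate")
    scores = []
    for _ in range(n_shuffles):
        a, b = rng.sample(seqs, 2)
        sa, sb = list(a), list(b)
        rng.shuffle(sa)
        rng.shuffle(sb)
        scores.append(align_score("".join(sa), "".join(sb), **align_kwargs))
    return statistics.mean(scores) + n_sigma * statistics.stdev(scores)


def all_vs_all(
    genes: list[CodingGene], threshold: float = 0.0, **align_kwargs
) -> ScoreTable:
    """Symmetric protein-similarity score table over all unordered pairs.

    Self-comparisons are excluded; pairs scoring below ``threshold`` are
    absent from the table. Keys are canonical (min id, max id) tuples.
    """
    if len(genes) < 2:
        raise ValueError("all_vs_all requires at least 2 genes")
    table: ScoreTable = {}
    for i, ga in enumerate(genes):
        for gb in genes[i + 1 :]:
            s = align_score(ga.protein, gb.protein, **align_kwargs)
            if s >= threshold:
                key = (ga.id, gb.id) if ga.id < gb.id else (gb.id, ga.id)
                table[key] = s
    return table


def _best_partners(scores: ScoreTable) -> dict[str, set[str]]:
    """Per gene, the set of partners attaining its maximal score."""
    best: dict[str, tuple[float, set[str]]] = {}
    for (a, b), s in scores.items():
        for x, y in ((a, b), (b, a)):
            cur = best.get(x)
            if cur is None or s > cur[0]:
                best[x] = (s, {y})
            elif s == cur[0]:
                cur[1].add(y)
    return {g: partners for g, (_, partners) in best.items()}


def reciprocal_best_hits(scores: ScoreTable) -> list[DuplicationPair]:
    """Emit (a, b) iff each is among the other's top-scoring partners.

    Equal top scores keep all tied pairs; output is sorted by canonical id
    pair, so it is invariant to input gene order.
    """
    best = _best_partners(scores)
    pairs = []
    for (a, b), s in scores.items():
        if b in best.get(a, ()) and a in best.get(b, ()):
            pairs.append(DuplicationPair(a, b, s))
    pairs.sort(key=lambda p: (p.id_a, p.id_b))
    return pairs


def classify_pairs(
    pairs: list[DuplicationPair],
    chromosomes: dict[str, str],
    n_genes_total: int | None = None,
) -> tuple[list[DuplicationPair], dict]:
    """Assign intra/inter-chromosomal kinds and compute a duplication census.

    A pair is intra_chromosomal iff both chromosomes are known and equal;
    inter_chromosomal iff both known and different; unplaced otherwise.
    The census reports the number and fraction of genes in any pair and
    per-chromosome pair counts.
    """
    for p in pairs:
        p.chromosome_a = chromosomes.get(p.id_a)
        p.chromosome_b = chromosomes.get(p.id_b)
        if p.chromosome_a is None or p.chromosome_b is None:
            p.kind = "unplaced"
        elif p.chromosome_a == p.chromosome_b:
            p.kind = "intra_chromosomal"
        else:
            p.kind = "inter_chromosomal"

    genes_in_pairs = {g for p in pairs for g in (p.id_a, p.id_b)}
    per_chrom: dict[str, int] = {}
    for p in pairs:
        if p.kind == "intra_chromosomal":
            per_chrom[p.chromosome_a] = per_chrom.get(p.chromosome_a, 0) + 1
    n_intra = sum(1 for p in pairs if p.kind == "intra_chromosomal")
    census = {
        "n_pairs": len(pairs),
        "n_genes_duplicated": len(genes_in_pairs),
        "fraction_duplicated": (
            len(genes_in_pairs) / n_genes_total if n_genes_total else None
        ),
        "n_intra_chromosomal": n_intra,
        "n_inter_chromosomal": sum(1 for p in pairs if p.kind == "inter_chromosomal"),
        "n_unplaced": sum(1 for p in pairs if p.kind == "unplaced"),
        "intra_pairs_per_chromosome": per_chrom,
    }
    return pairs, census
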