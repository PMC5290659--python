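#!/usr/bin/env python
"""Call duplicate gene pairs by reciprocal best hits.

Reads the simulated family from results/family/, adds two unrelated
decoy genes, calibrates the chance-similarity score threshold by
permutation, runs the all-vs-all scan plus RBH, and classifies pairs as
intra-/inter-chromosomal. Writes results/duplication/.
"""

from dataclasses import asdict
from pathlib import Path

from ugtevol.duplication import (
    all_vs_all,
    calibrate_score_threshold,
    classify_pairs,
    reciprocal_best_hits,
)
from ugtevol.io import read_chromosome_table, read_coding_genes, write_tsv
from ugtevol.sequence import CodingGene
from ugtevol.simulate import random_cds

FAMILY = Path(__file__).resolve().parent.parent / "results" / "family"
OUT = Path(__file__).resolve().parent.parent / "results" / "duplication"
SEED = 2024


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    genes = read_coding_genes(FAMILY / "genes_cds.fasta", FAMILY / "chromosomes.tsv")
    decoys = [CodingGene(f"decoy{i}", random_cds(500, seed=SEED + 900 + i)) for i in range(2)]
    everything = genes + decoys

    threshold = calibrate_score_threshold(
        {g.id: g.protein for g in everything}, seed=SEED
    )
    scores = all_vs_all(everything, threshold=threshold)
    pairs = reciprocal_best_hits(scores)
    chroms = read_chromosome_table(FAMILY / "chromosomes.tsv")
    pairs, census = classify_pairs(pairs, chroms, n_genes_total=len(everything))

    write_tsv(
        OUT / "scores.tsv",
        [{"id_a": a, "id_b": b, "score": s} for (a, b), s in sorted(scores.items())],
        ["id_a", "id_b", "score"],
    )
    write_tsv(
        OUT / "duplication_pairs.tsv",
        [asdict(p) for p in pairs],
        ["id_a", "id_b", "score", "chromosome_a", "chromosome_b", "kind"],
    )

    print(f"calibrated score threshold: {threshold:.1f}")
    print(f"{len(scores)} pairs pass the threshold "
          f"(decoys excluded: {all('decoy' not in a and 'decoy' not in b for a, b in scores)})")
    print(f"RBH duplicate pairs: {[(p.id_a, p.id_b, p.kind) for p in pairs]}")
    print(f"census: {census['n_genes_duplicated']}/{len(everything)} genes in a duplicate pair "
          f"({census['n_intra_chromosomal']} intra-, {census['n_inter_chromosomal']} inter-chromosomal)")


if __name__ == "__main__":
    main()
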