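"""All-vs-all scoring, reciprocal best hits, chromosome classification."""

import random

import pytest

from ugtevol.duplication import (
    all_vs_all,
    calibrate_score_threshold,
    classify_pairs,
    DuplicationPair,
    reciprocal_best_hits,
)
from ugtevol.sequence import CodingGene
from ugtevol.simulate import evolve_pair, random_cds


def test_two_identical_genes_single_max_pair():
    cds = random_cds(60, seed=1)
    genes = [CodingGene("a", cds), CodingGene("b", cds)]
    table = all_vs_all(genes)
    assert set(table) == {("a", "b")}


def test_pair_count_bound(small_family):
    genes, _ = small_family
    table = all_vs_all(genes)
    n = len(genes)
    assert len(table) <= n * (n - 1) // 2


def test_all_vs_all_needs_two_genes():
    with pytest.raises(ValueError):
        all_vs_all([CodingGene("a", random_cds(30, seed=0))])


def test_threshold_drops_unrelated_decoy():
    anc = random_cds(150, seed=2)
    a, b, _ = evolve_pair(anc, t_mya=5, omega=0.3, seed=3)
    decoy = random_cds(150, seed=999)
    genes = [CodingGene("a", a), CodingGene("b", b), CodingGene("c", decoy)]
    threshold = calibrate_score_threshold({g.id: g.protein for g in genes}, seed=0)
    table = all_vs_all(genes, threshold=threshold)
    assert set(table) == {("a", "b")}


def test_rbh_mutual_top_condition():
    scores = {("A", "B"): 100.0, ("A", "C"): 50.0, ("B", "C"): 40.0}
    pairs = reciprocal_best_hits(scores)
    assert [(p.id_a, p.id_b) for p in pairs] == [("A", "B")]


def test_rbh_chain_breaks_mutuality():
    # A's top is B, but B's top is C: no pair contains A
    scores = {("A", "B"): 60.0, ("B", "C"): 80.0, ("A", "C"): 10.0}
    pairs = reciprocal_best_hits(scores)
    assert all("A" not in (p.id_a, p.id_b) for p in pairs)
    assert [(p.id_a, p.id_b) for p in pairs] == [("B", "C")]


def test_rbh_empty_and_ties():
    assert reciprocal_best_hits({}) == []
    tied = {("A", "B"): 50.0, ("A", "C"): 50.0, ("B", "C"): 10.0}
    pairs = reciprocal_best_hits(tied)
    assert [(p.id_a, p.id_b) for p in pairs] == [("A", "B"), ("A", "C")]


def test_rbh_invariant_to_input_order(rng):
    items = [(("g%02d" % a, "g%02d" % b), rng.uniform(10, 100))
             for a in range(8) for b in range(a + 1, 8)]
    expected = None
    for _ in range(5):
        rng.shuffle(items)
        pairs = reciprocal_best_hits(dict(items))
        got = [(p.id_a, p.id_b, p.score) for p in pairs]
        if expected is None:
            expected = got
        assert got == expected


def test_rbh_recall_on_simulated_duplicates():
    """Every true duplicate pair is recovered when decoys sit below threshold."""
    rng = random.Random(5)
    genes = []
    true_pairs = set()
    for fam in range(6):
        anc = random_cds(150, seed=rng.randrange(2**31))
        a, b, _ = evolve_pair(anc, t_mya=10, omega=0.3, seed=rng.randrange(2**31))
        ida, idb = f"f{fam}a", f"f{fam}b"
        genes += [CodingGene(ida, a), CodingGene(idb, b)]
        true_pairs.add((ida, idb))
    for d in range(4):
        genes.append(CodingGene(f"z_decoy{d}", random_cds(150, seed=10_000 + d)))
    threshold = calibrate_score_threshold({g.id: g.protein for g in genes}, seed=1)
    pairs = reciprocal_best_hits(all_vs_all(genes, threshold=threshold))
    found = {(p.id_a, p.id_b) for p in pairs}
    recall = len(found & true_pairs) / len(true_pairs)
    assert recall >= 0.95
    assert all(not (a.startswith("z_") or b.startswith("z_")) for a, b in found)


def test_rbh_scores_respect_threshold(small_family):
    genes, _ = small_family
    table = all_vs_all(genes, threshold=100.0)
    for p in reciprocal_best_hits(table):
        assert p.score >= 100.0


@pytest.mark.parametrize(
    "chrom_a,chrom_b,kind",
    [
        ("Chr1", "Chr1", "intra_chromosomal"),
        ("Chr8", "Chr14", "inter_chromosomal"),
        (None, "Chr2", "unplaced"),
    ],
)
def test_classify_kinds(chrom_a, chrom_b, kind):
    chroms = {}
    if chrom_a:
        chroms["a"] = chrom_a
    if chrom_b:
        chroms["b"] = chrom_b
    pairs, census = classify_pairs([DuplicationPair("a", "b", 50.0)], chroms, 2)
    assert pairs[0].kind == kind


def test_census_counts():
    pairs = [
        DuplicationPair("a", "b", 50.0),
        DuplicationPair("b", "c", 40.0),
    ]
    chroms = {"a": "Chr1", "b": "Chr1", "c": "Chr3"}
    _, census = classify_pairs(pairs, chroms, n_genes_total=4)
    assert census["n_genes_duplicated"] == 3
    assert census["fraction_duplicated"] == pytest.approx(0.75)
    assert census["n_intra_chromosomal"] == 1
    assert census["intra_pairs_per_chromosome"] == {"Chr1": 1}
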