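"""NG86 counting, Jukes-Cantor correction, filters and selection classes."""

import math
import random

import pytest

from _oracles import (
    SENSE_CODONS,
    oracle_diffs,
    oracle_kaks,
    oracle_sites,
    random_codon_pair_list,
)
from ugtevol.align import CodonPairAlignment
from ugtevol.clock import divergence_time, k_from_time
from ugtevol.kaks import (
    classify_selection,
    compute_kaks,
    count_differences,
    count_sites,
    filter_pairs,
    jukes_cantor,
    KaKsResult,
    SaturationError,
)


@pytest.mark.parametrize(
    "codon,expected_s",
    [("TTT", 1 / 3), ("ATG", 0.0), ("TGG", 0.0)],
)
def test_count_sites_examples(codon, expected_s):
    s, n = count_sites(codon)
    assert s == pytest.approx(expected_s)
    assert s + n <= 3 + 1e-12


def test_count_sites_matches_enumeration_for_all_sense_codons():
    for codon in SENSE_CODONS:
        assert count_sites(codon) == pytest.approx(oracle_sites(codon))


def test_count_sites_rejects_stop_and_ambiguity():
    with pytest.raises(ValueError):
        count_sites("TAA")
    with pytest.raises(ValueError):
        count_sites("ANG")


@pytest.mark.parametrize(
    "ca,cb,expected",
    [
        ("TTT", "TTT", (0.0, 0.0)),
        ("TTT", "TTA", (0.0, 1.0)),  # Phe -> Leu, nonsynonymous
        ("TTT", "GTA", (0.5, 1.5)),  # two 2-step pathways averaged
    ],
)
def test_count_differences_examples(ca, cb, expected):
    assert count_differences(ca, cb) == pytest.approx(expected)


def test_count_differences_matches_enumeration(rng):
    for _ in range(300):
        ca = rng.choice(SENSE_CODONS)
        cb = rng.choice(SENSE_CODONS)
        try:
            expected = oracle_diffs(ca, cb)
        except ValueError:
            with pytest.raises(ValueError):
                count_differences(ca, cb)
            continue
        got = count_differences(ca, cb)
        assert got == pytest.approx(expected)
        k = sum(a != b for a, b in zip(ca, cb))
        assert sum(got) == pytest.approx(k)


@pytest.mark.parametrize(
    "p,expected",
    [(0.0, 0.0), (0.05, 0.0517), (0.45, None)],
)
def test_jukes_cantor_values(p, expected):
    d = jukes_cantor(p)
    if expected is not None:
        assert d == pytest.approx(expected, abs=1e-4)
    assert d >= p


def test_jukes_cantor_domain():
    assert jukes_cantor(0.74) > 3  # large but finite near saturation
    with pytest.raises(SaturationError):
        jukes_cantor(0.75)
    with pytest.raises(SaturationError):
        jukes_cantor(-0.01)


def test_identical_sequences_zero_distances():
    codons = ["ATG", "AAA", "TTT", "GGC"]
    res = compute_kaks(CodonPairAlignment("a", "b", codons, codons))
    assert res.Ks == 0 and res.Ka == 0
    assert res.ratio is None


def test_compute_kaks_matches_bruteforce_oracle():
    rng = random.Random(404)
    for _ in range(20):
        cas, cbs = random_codon_pair_list(30, rng)
        res = compute_kaks(CodonPairAlignment("a", "b", cas, cbs))
        exp = oracle_kaks(cas, cbs)
        for field in ("S", "N", "Sd", "Nd", "pS", "pN", "Ks", "Ka"):
            assert getattr(res, field) == pytest.approx(exp[field], abs=1e-9)


def test_compute_kaks_symmetric(rng):
    cas, cbs = random_codon_pair_list(40, rng)
    fwd = compute_kaks(CodonPairAlignment("a", "b", cas, cbs))
    rev = compute_kaks(CodonPairAlignment("b", "a", cbs, cas))
    assert fwd.Ks == pytest.approx(rev.Ks)
    assert fwd.Ka == pytest.approx(rev.Ka)
    assert fwd.S == pytest.approx(rev.S)


def test_site_sum_bounded_by_three_per_codon(rng):
    cas, cbs = random_codon_pair_list(25, rng)
    res = compute_kaks(CodonPairAlignment("a", "b", cas, cbs))
    assert res.S + res.N <= 3 * res.n_codons + 1e-9
    assert res.Sd <= res.S and res.Nd <= res.N


def test_biopython_crosscheck_on_stop_distant_codons():
    """Where stop conventions cannot bite, an independent library agrees."""
    from Bio.Align.analysis import _count_site_NG86, _count_diff_NG86
    from Bio.Data import CodonTable

    table = CodonTable.unambiguous_dna_by_id[1]
    stops = set(table.stop_codons)

    def stop_distant(codon):
        return all(
            codon[:i] + b + codon[i + 1 :] not in stops
            for i in range(3)
            for b in "ACGT"
        )

    safe = [c for c in SENSE_CODONS if stop_distant(c)]
    for codon in safe:
        s, n = count_sites(codon)
        bs, bn = _count_site_NG86([codon], table)
        assert s == pytest.approx(bs) and n == pytest.approx(bn)
    rng = random.Random(7)
    for _ in range(100):
        ca, cb = rng.choice(safe), rng.choice(safe)
        # pathways must also avoid stops for conventions to coincide
        try:
            sd, nd = count_differences(ca, cb)
        except ValueError:
            continue
        k = sum(a != b for a, b in zip(ca, cb))
        bsd, bnd = _count_diff_NG86(ca, cb, table)
        if k < 3 or math.isclose(bsd + bnd, k):
            assert sd == pytest.approx(bsd) and nd == pytest.approx(bnd)


@pytest.mark.parametrize(
    "ks,status",
    [
        (0.0005, "removed_low_ks"),
        (2.1, "removed_high_ks"),
        (0.493, "retained"),
        (None, "undefined"),
    ],
)
def test_filter_rules(ks, status):
    r = KaKsResult("a", "b", 10, 7, 23, 1, 1, 0.1, 0.04, ks, 0.05, None)
    filter_pairs([r])
    assert r.filter_status == status


@pytest.mark.parametrize(
    "ratio,band,expected",
    [
        (0.306, 0.0, "purifying"),
        (1.5, 0.0, "positive"),
        (1.0, 0.0, "neutral"),
        (0.9, 0.2, "neutral"),
        (None, 0.0, "unclassified"),
    ],
)
def test_classify_selection(ratio, band, expected):
    assert classify_selection(ratio, band) == expected


def test_classify_selection_rejects_negative():
    with pytest.raises(ValueError):
        classify_selection(-0.1)


def test_ks_time_round_trip():
    for ks in (0.031, 0.2, 0.493, 1.997):
        t = divergence_time(ks)
        assert k_from_time(t) == pytest.approx(ks, rel=1e-12)
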