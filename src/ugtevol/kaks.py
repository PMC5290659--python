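"""Nei-Gojobori (1986) Ka/Ks estimation with Jukes-Cantor correction.

The NG86 counting method classifies every codon site by the fraction of
its three possible single-nucleotide changes that are synonymous, and
classifies observed codon differences by averaging the synonymous /
nonsynonymous step counts over all equal-weight mutational pathways
between the two codons. Proportions of differences per site are then
corrected for multiple hits with the Jukes-Cantor formula, giving Ks
(= dS) and Ka (= dN); their ratio is the selection indicator omega.

Stop-codon conventions (the MEGA-compatible "unweighted pathway" variant):

* site counting — single-nucleotide mutations that create a stop codon
  contribute to neither the synonymous nor the nonsynonymous site count,
  so s + n for a stop-adjacent codon is slightly below 3;
* pathway averaging — mutational pathways passing through a stop codon
  are excluded and the remaining pathways re-weighted equally; a codon
  pair with no stop-free pathway is skipped entirely (sites and
  differences) for that pair.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache
from itertools import permutations

from .align import CodonPairAlignment
from .sequence import STANDARD_TABLE

__all__ = [
    "KaKsResult",
    "count_sites",
    "count_differences",
    "jukes_cantor",
    "compute_kaks",
    "filter_pairs",
    "classify_selection",
    "KS_LOW_CUTOFF",
    "KS_HIGH_CUTOFF",
    "SaturationError",
]

# Filtration rules for Ks-based dating: near-zero Ks (allelic noise,
# assembly artefacts) and saturated Ks are removed before clock dating.
KS_LOW_CUTOFF = 0.001
KS_HIGH_CUTOFF = 2.0

_BASES = "ACGT"
_STOPS = frozenset(STANDARD_TABLE.stop_codons)
_FWD = dict(STANDARD_TABLE.forward_table)


class SaturationError(ValueError):
    """Proportion of differences >= 3/4: Jukes-Cantor distance undefined."""


def _check_sense(codon: str) -> str:
    codon = codon.upper()
    if len(codon) != 3 or any(b not in _BASES for b in codon):
        raise ValueError(f"not an unambiguous codon: {codon!r}")
    if codon in _STOPS:
        raise ValueError(f"stop codon {codon} is not a sense codon")
    return codon


@lru_cache(maxsize=64)
def count_sites(codon: str) -> tuple[float, float]:
    """Synonymous and nonsynonymous site counts (s, n) of one sense codon.

    Each position contributes 1/3 site per possible nucleotide change;
    changes to stop codons are dropped, so s + n <= 3.
    """
    codon = _check_sense(codon)
    aa = _FWD[codon]
    s = n = 0.0
    for i, base in enumerate(codon):
        for alt in _BASES:
            if alt == base:
                continue
            mutant = codon[:i] + alt + codon[i + 1 :]
            if mutant in _STOPS:
                continue
            if _FWD[mutant] == aa:
                s += 1 / 3
            else:
                n += 1 / 3
    return s, n


@lru_cache(maxsize=4096)
def count_differences(codon_a: str, codon_b: str) -> tuple[float, float]:
    """Pathway-averaged (sd, nd) difference counts between two sense codons.

    With k differing positions, the k! single-step pathways are weighted
    equally; pathways through stop codons are excluded. Raises
    :class:`ValueError` if no legal pathway exists (callers skip the codon
    pair).
    """
    codon_a = _check_sense(codon_a)
    codon_b = _check_sense(codon_b)
    diff = [i for i in range(3) if codon_a[i] != codon_b[i]]
    if not diff:
        return 0.0, 0.0

    legal_paths = []
    for order in permutations(diff):
        current = codon_a
        steps = []
        ok = True
        for i in order:
            nxt = current[:i] + codon_b[i] + current[i + 1 :]
            if nxt in _STOPS:
                ok = False
                break
            steps.append((current, nxt))
            current = nxt
        if ok:
            legal_paths.append(steps)
    if not legal_paths:
        raise ValueError(f"no stop-free pathway between {codon_a} and {codon_b}")

    sd = nd = 0.0
    w = 1.0 / len(legal_paths)
    for steps in legal_paths:
        for frm, to in steps:
            if _FWD[frm] == _FWD[to]:
                sd += w
            else:
                nd += w
    return sd, nd


def jukes_cantor(p: float) -> float:
    """Jukes-Cantor multiple-hit correction d = -(3/4) ln(1 - 4p/3)."""
    if not 0 <= p < 0.75:
        raise SaturationError(f"proportion {p} outside [0, 0.75)")
    return -0.75 * math.log1p(-4.0 * p / 3.0)


@dataclass
class KaKsResult:
    """NG86 counts, corrected distances and classification for one pair."""

    id_a: str
    id_b: str
    n_codons: int
    S: float
    N: float
    Sd: float
    Nd: float
    pS: float
    pN: float
    Ks: float | None
    Ka: float | None
    ratio: float | None
    filter_status: str = "retained"  # retained | removed_low_ks | removed_high_ks | undefined
    selection_class: str = "unclassified"  # purifying | neutral | positive | unclassified


def compute_kaks(aln: CodonPairAlignment) -> KaKsResult:
    """NG86 Ka/Ks for one paired-codon alignment.

    Site counts are averaged over the two sequences; difference counts are
    summed over columns. Saturated proportions (>= 0.75) yield ``None``
    distances and filter_status ``undefined``; Ks == 0 yields an undefined
    ratio.
    """
    if aln.n_codons < 1:
        raise ValueError("alignment has no codons")

    S = N = Sd = Nd = 0.0
    used = 0
    for ca, cb in zip(aln.codons_a, aln.codons_b):
        try:
            sd, nd = count_differences(ca, cb)
        except ValueError:
            continue  # no stop-free pathway: skip column for this pair
        sa, na = count_sites(ca)
        sb, nb = count_sites(cb)
        S += (sa + sb) / 2
        N += (na + nb) / 2
        Sd += sd
        Nd += nd
        used += 1
    if used == 0:
        raise ValueError("no usable codon columns")

    pS = Sd / S if S > 0 else 0.0
    pN = Nd / N if N > 0 else 0.0
    try:
        Ks: float | None = jukes_cantor(pS)
        Ka: float | None = jukes_cantor(pN)
    except SaturationError:
        return KaKsResult(
            aln.id_a, aln.id_b, used, S, N, Sd, Nd, pS, pN,
            None, None, None, filter_status="undefined",
        )
    ratio = (Ka / Ks) if Ks > 0 else None
    return KaKsResult(aln.id_a, aln.id_b, used, S, N, Sd, Nd, pS, pN, Ks, Ka, ratio)


def filter_pairs(results: list[KaKsResult]) -> list[KaKsResult]:
    """Apply the Ks filtration rules in place and return the list.

    Ks < 0.001 (indistinguishable from zero divergence) -> removed_low_ks;
    Ks > 2 (saturation regime) -> removed_high_ks; saturated/undefined Ks
    stays ``undefined``; everything else is retained.
    """
    for r in results:
        if r.Ks is None:
            r.filter_status = "undefined"
        elif r.Ks < KS_LOW_CUTOFF:
            r.filter_status = "removed_low_ks"
        elif r.Ks > KS_HIGH_CUTOFF:
            r.filter_status = "removed_high_ks"
        else:
            r.filter_status = "retained"
    return results


def classify_selection(ratio: float | None, neutral_band: float = 0.0) -> str:
    """Classify a Ka/Ks ratio: purifying (<1), neutral (~1), positive (>1).

    ``neutral_band`` widens the neutral class to [1-band, 1+band]; the
    default band of 0 treats exactly 1 as neutral. ``None`` (undefined
    ratio) is unclassified.
    """
    if ratio is None:
        return "unclassified"
    if ratio < 0:
        raise ValueError(f"negative Ka/Ks ratio {ratio}")
    if ratio < 1 - neutral_band:
        return "purifying"
    if ratio > 1 + neutral_band:
        return "positive"
    return "neutral"


def classify_results(results: list[KaKsResult], neutral_band: float = 0.0) -> list[KaKsResult]:
    """Attach selection classes to a list of results (in place)."""
    for r in results:
        r.selection_class = classify_selection(r.ratio, neutral_band)
    return results
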