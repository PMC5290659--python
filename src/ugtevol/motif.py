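"""PSPG-box detection: profile building and window scanning.

Plant family-1 UGTs carry a 44-residue C-terminal signature (the plant
secondary product glycosyltransferase box) involved in sugar-donor
binding. This module builds a position-specific log-odds profile from
seed motifs and scans proteins for the best-scoring 44-residue window,
extracting the window plus flanking context for reduced phylogenies.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = ["MOTIF_LEN", "MotifProfile", "MotifHit", "build_profile", "scan_pspg"]

MOTIF_LEN = 44
AA = "ACDEFGHIKLMNPQRSTVWY"
_AA_INDEX = {a: i for i, a in enumerate(AA)}


@dataclass
class MotifProfile:
    """Position-specific log-odds scores (length x 20), uniform background."""

    log_odds: np.ndarray  # shape (motif_len, 20), log2 odds
    consensus: str

    @property
    def length(self) -> int:
        return self.log_odds.shape[0]

    @property
    def max_score(self) -> float:
        return float(self.log_odds.max(axis=1).sum())

    def score(self, window: str) -> float:
        if len(window) != self.length:
            raise ValueError(f"window length {len(window)} != profile length {self.length}")
        idx = [_AA_INDEX[a] for a in window]
        return float(self.log_odds[np.arange(self.length), idx].sum())


@dataclass
class MotifHit:
    """One motif occurrence, 1-based inclusive coordinates."""

    protein_id: str
    start: int
    end: int
    score: float
    window: str
    flank_up: str
    flank_down: str


def build_profile(seed_motifs: list[str], pseudocount: float = 1.0) -> MotifProfile:
    """Log-odds profile from equal-length seeds with Laplace pseudocounts.

    Per position, P(aa) = (count + pseudocount) / (n_seeds + 20·pseudocount)
    scored against a uniform 1/20 background in log2 units. Duplicate seeds
    do not change the profile shape relative to a single seed.
    """
    if not seed_motifs:
        raise ValueError("need at least one seed motif")
    length = len(seed_motifs[0])
    unique = list(dict.fromkeys(seed_motifs))  # idempotent under duplication
    for s in unique:
        if len(s) != length:
            raise ValueError(f"seed {s!r} has length {len(s)}, expected {length}")
        bad = set(s) - set(AA)
        if bad:
            raise ValueError(f"non-standard residues in seed: {sorted(bad)}")

    counts = np.full((length, 20), pseudocount)
    for s in unique:
        for i, a in enumerate(s):
            counts[i, _AA_INDEX[a]] += 1
    probs = counts / counts.sum(axis=1, keepdims=True)
    log_odds = np.log2(probs / 0.05)
    consensus = "".join(AA[j] for j in log_odds.argmax(axis=1))
    return MotifProfile(log_odds, consensus)


def default_threshold(profile: MotifProfile, fraction: float = 0.6) -> float:
    """Detection threshold: a fraction of the profile's maximal self-score."""
    return fraction * profile.max_score


def scan_pspg(
    protein_id: str,
    sequence: str,
    profile: MotifProfile,
    threshold: float | None = None,
    flank_len: int = 50,
) -> list[MotifHit]:
    """Best-scoring profile window(s) above threshold in one protein.

    Returns the maximal-scoring window (all of them on exact ties) if it
    reaches the threshold, with up to ``flank_len`` residues of context on
    each side (truncated at the sequence ends). Proteins shorter than the
    profile are an error.
    """
    L = profile.length
    if len(sequence) < L:
        raise ValueError(f"{protein_id}: protein shorter than the {L}-residue profile")
    if threshold is None:
        threshold = default_threshold(profile)

    scores = [
        profile.score(sequence[i : i + L]) for i in range(len(sequence) - L + 1)
    ]
    best = max(scores)
    if best < threshold:
        return []
    hits = []
    for i, s in enumerate(scores):
        if not math.isclose(s, best, rel_tol=0, abs_tol=1e-9):
            continue
        start, end = i + 1, i + L  # 1-based inclusive
        hits.append(
            MotifHit(
                protein_id=protein_id,
                start=start,
                end=end,
                score=s,
                window=sequence[i : i + L],
                flank_up=sequence[max(0, i - flank_len) : i],
                flank_down=sequence[i + L : i + L + flank_len],
            )
        )
    return hits
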