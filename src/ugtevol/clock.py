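"""Strict molecular clock: synonymous divergence <-> time.

Under a constant synonymous substitution rate r (substitutions per
synonymous site per year), two lineages separated t years ago accumulate
k = 2 r t substitutions per synonymous site between them, so
t_mya = k / (2 r) / 10^6. The default rate is 6.5e-9, a standard plant
nuclear-gene synonymous rate.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = ["DEFAULT_RATE", "DivergenceEstimate", "divergence_time", "k_from_time"]

DEFAULT_RATE = 6.5e-9


def divergence_time(k: float, r: float = DEFAULT_RATE) -> float:
    """Divergence time in million years: t = k / (2 r) / 10^6."""
    if k < 0:
        raise ValueError(f"negative divergence k={k}")
    if r <= 0:
        raise ValueError(f"substitution rate must be positive, got {r}")
    return k / (2.0 * r) / 1e6


def k_from_time(t_mya: float, r: float = DEFAULT_RATE) -> float:
    """Expected synonymous divergence after t million years: k = 2 r t 10^6."""
    if t_mya < 0:
        raise ValueError(f"negative time {t_mya}")
    if r <= 0:
        raise ValueError(f"substitution rate must be positive, got {r}")
    return t_mya * 1e6 * 2.0 * r


@dataclass
class DivergenceEstimate:
    """A dated gene pair: retained Ks converted to million years."""

    id_a: str
    id_b: str
    k: float
    r: float = DEFAULT_RATE

    @property
    def t_mya(self) -> float:
        return divergence_time(self.k, self.r)


def time_matrix_rows(
    estimates: list[DivergenceEstimate], ids: list[str]
) -> list[dict[str, str]]:
    """Lower-triangular pairwise time matrix rows, "N/A" for missing pairs.

    ``ids`` fixes row/column order; suitable for TSV export.
    """
    by_pair = {frozenset((e.id_a, e.id_b)): e.t_mya for e in estimates}
    rows = []
    for i, rid in enumerate(ids[1:], start=1):
        row: dict[str, str] = {"id": rid}
        for cid in ids[:i]:
            t = by_pair.get(frozenset((rid, cid)))
            row[cid] = "N/A" if t is None else f"{t:.2f}"
        rows.append(row)
    return rows
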