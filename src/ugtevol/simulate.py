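"""Codon-evolution simulator for gene families with known ground truth.

The generator emulates a family of duplicated coding sequences diverging
under a strict molecular clock at synonymous rate r with selection
intensity omega (dN/dS): single-nucleotide changes are proposed
uniformly and accepted with probability 1 if synonymous, omega if
nonsynonymous, 0 if they create a stop codon. Proposal counts are
Poisson-distributed and calibrated so that the expected pairwise
synonymous divergence of two lineages separated t MY ago is
k = 2 r t 10^6 per synonymous site — the quantity the NG86 estimator
and the clock module are meant to recover.

Duplication histories are combs: duplication times (MYA) sorted
descending, each spawning a lineage that evolves independently to the
present; the true divergence time of two genes is the spawn time of the
earlier-spawned one.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field

from .clock import DEFAULT_RATE, k_from_time
from .kaks import _FWD, _STOPS
from .sequence import CodingGene, translate_cds

__all__ = ["SimConfig", "PairTruth", "SimTruth", "random_cds", "evolve_pair", "simulate_family"]

_BASES = "ACGT"
_SENSE = sorted(_FWD)

# deterministic codon choice per residue, for motif embedding
_PREFERRED = {}
for _c in _SENSE:
    _PREFERRED.setdefault(_FWD[_c], _c)


@dataclass
class SimConfig:
    """Study conditions for one simulated family."""

    n_codons: int = 300
    omega: float = 0.3
    rate_r: float = DEFAULT_RATE
    times_mya: list[float] = field(default_factory=lambda: [5.0, 15.0, 40.0])
    seed: int = 0
    motif: tuple[str, int] | None = None  # (44-residue string, 1-based protein pos)
    chromosomes: list[str] | None = None

    def __post_init__(self) -> None:
        if self.omega < 0:
            raise ValueError("omega must be >= 0")
        if any(t < 0 for t in self.times_mya):
            raise ValueError("duplication times must be >= 0")
        if self.motif is not None and self.n_codons < len(self.motif[0]):
            raise ValueError("n_codons too small for the requested motif")


@dataclass
class PairTruth:
    id_a: str
    id_b: str
    true_t_mya: float
    true_expected_ks: float
    true_omega: float


@dataclass
class SimTruth:
    """Ground truth for a simulated family."""

    pairs: list[PairTruth]
    substitutions: dict[str, dict[str, int]]  # per gene: accepted syn/nonsyn counts


def random_cds(n_codons: int, seed: int = 0) -> str:
    """A random valid CDS: ATG start, uniform sense codons, terminal stop.

    Output length is 3·n_codons (the start and, for n_codons >= 2, the
    terminal stop are counted among the codons).
    """
    if n_codons < 1:
        raise ValueError("need at least one codon")
    rng = random.Random(seed)
    middle = [rng.choice(_SENSE) for _ in range(n_codons - 2)]
    if n_codons == 1:
        return "ATG"
    return "ATG" + "".join(middle) + rng.choice(sorted(_STOPS))


def _evolve_lineage(
    cds: str,
    syn_per_site: float,
    omega: float,
    rng: random.Random,
    frozen: frozenset[int] = frozenset(),
) -> tuple[str, int, int]:
    """Accumulate substitutions on one lineage.

    ``syn_per_site`` is the target expected number of accepted synonymous
    substitutions per synonymous site of the evolving region; codon
    indices in ``frozen`` (a conserved motif) never change. Returns
    (sequence, n_syn, n_nonsyn).
    """
    has_stop = cds[-3:] in _STOPS
    codons = [cds[i : i + 3] for i in range(0, len(cds), 3)]
    n_mut = len(codons) - 1 if has_stop else len(codons)
    mutable = [i for i in range(n_mut) if i not in frozen]
    sites = 3 * len(mutable)

    # relative acceptance 1 : omega for synonymous : nonsynonymous changes,
    # rescaled into [0, 1]; the proposal budget is inflated by 1/acc_syn so
    # the expected accepted synonymous substitutions stay syn_per_site x S
    # for any omega (including omega > 1).
    acc_syn = 1.0 if omega <= 1 else 1.0 / omega
    acc_nonsyn = omega if omega <= 1 else 1.0

    n_proposals = _poisson(syn_per_site * sites / acc_syn, rng)
    n_syn = n_nonsyn = 0
    for _ in range(n_proposals):
        pos = rng.randrange(sites)
        mi, off = divmod(pos, 3)
        ci = mutable[mi]
        codon = codons[ci]
        alt = rng.choice([b for b in _BASES if b != codon[off]])
        mutant = codon[:off] + alt + codon[off + 1 :]
        if mutant in _STOPS:
            continue
        if _FWD[mutant] == _FWD[codon]:
            if acc_syn >= 1.0 or rng.random() < acc_syn:
                codons[ci] = mutant
                n_syn += 1
        elif rng.random() < acc_nonsyn:
            codons[ci] = mutant
            n_nonsyn += 1
    return "".join(codons), n_syn, n_nonsyn


def _poisson(lam: float, rng: random.Random) -> int:
    """Poisson sample via inversion (lam moderate) or normal approximation."""
    if lam <= 0:
        return 0
    if lam > 700:  # avoid exp underflow; CLT is excellent here
        return max(0, round(rng.gauss(lam, lam**0.5)))
    L = 2.718281828459045 ** (-lam)
    k, p = 0, 1.0
    while True:
        p *= rng.random()
        if p <= L:
            return k
        k += 1


def _embed_motif(cds: str, motif: str, position: int) -> str:
    """Overwrite codons so the protein carries ``motif`` at ``position`` (1-based)."""
    codons = [cds[i : i + 3] for i in range(0, len(cds), 3)]
    for k, aa in enumerate(motif):
        codons[position - 1 + k] = _PREFERRED[aa]
    return "".join(codons)


def evolve_pair(
    ancestor: str,
    t_mya: float,
    omega: float,
    rate_r: float = DEFAULT_RATE,
    seed: int = 0,
) -> tuple[str, str, SimTruth]:
    """Evolve two descendant lineages of ``ancestor`` for t million years each."""
    translate_cds(ancestor)  # validates the CDS
    k = k_from_time(t_mya, rate_r)
    rng = random.Random(seed)
    a, sa, na = _evolve_lineage(ancestor, k / 2, omega, rng)
    b, sb, nb = _evolve_lineage(ancestor, k / 2, omega, rng)
    truth = SimTruth(
        pairs=[PairTruth("a", "b", t_mya, k, omega)],
        substitutions={
            "a": {"syn": sa, "nonsyn": na},
            "b": {"syn": sb, "nonsyn": nb},
        },
    )
    return a, b, truth


def simulate_family(config: SimConfig) -> tuple[list[CodingGene], SimTruth]:
    """Simulate a duplicated gene family along a comb genealogy.

    One ancestor is duplicated at each time in ``times_mya``; every copy
    then evolves to the present. Genes are named g1..gN in spawn order
    (oldest offshoot first, the trunk last); chromosomes are assigned
    cyclically if configured. The motif, if any, is embedded at its stated
    protein position in the ancestor and held invariant during evolution
    (a conserved signature), so every copy carries it exactly; the
    conserved window correspondingly dilutes realized whole-gene
    divergence by roughly its share of the sequence.
    """
    rng = random.Random(config.seed)
    times = sorted(config.times_mya, reverse=True)
    trunk = random_cds(config.n_codons, seed=rng.randrange(2**31))
    frozen = frozenset()
    if config.motif is not None:
        motif_seq, pos = config.motif
        trunk = _embed_motif(trunk, motif_seq, pos)
        frozen = frozenset(range(pos - 1, pos - 1 + len(motif_seq)))

    spawned: list[tuple[str, str, float]] = []  # (name, cds, spawn time)
    counts: dict[str, dict[str, int]] = {}
    current_t = times[0] if times else 0.0
    for i, t_spawn in enumerate(times):
        # trunk evolves from current_t down to t_spawn
        k_seg = k_from_time(current_t - t_spawn, config.rate_r)
        trunk, _, _ = _evolve_lineage(trunk, k_seg / 2, config.omega, rng, frozen)
        # offshoot evolves from t_spawn to the present
        name = f"g{i + 1}"
        k_off = k_from_time(t_spawn, config.rate_r)
        seq, s, n = _evolve_lineage(trunk, k_off / 2, config.omega, rng, frozen)
        spawned.append((name, seq, t_spawn))
        counts[name] = {"syn": s, "nonsyn": n}
        current_t = t_spawn
    # trunk itself down to the present
    k_seg = k_from_time(current_t, config.rate_r)
    trunk, s, n = _evolve_lineage(trunk, k_seg / 2, config.omega, rng, frozen)
    trunk_name = f"g{len(times) + 1}"
    spawned.append((trunk_name, trunk, 0.0))
    counts[trunk_name] = {"syn": s, "nonsyn": n}

    genes = []
    for idx, (name, seq, _) in enumerate(spawned):
        chrom = None
        if config.chromosomes:
            chrom = config.chromosomes[idx % len(config.chromosomes)]
        genes.append(CodingGene(id=name, cds=seq, chromosome=chrom))

    pairs = []
    for i in range(len(spawned)):
        for j in range(i + 1, len(spawned)):
            na_, _, ta = spawned[i]
            nb_, _, tb = spawned[j]
            t_true = max(ta, tb)
            pairs.append(
                PairTruth(na_, nb_, t_true, k_from_time(t_true, config.rate_r), config.omega)
            )
    return genes, SimTruth(pairs=pairs, substitutions=counts)
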