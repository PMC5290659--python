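"""Independent brute-force oracles, sharing no code with the package.

Everything here is written naively from first principles (enumeration,
full-matrix DP, exhaustive search) so that agreement with the package is
a genuine two-route check.
"""

from __future__ import annotations

import itertools
import math
import random

from Bio.Data import CodonTable

_TABLE = CodonTable.unambiguous_dna_by_id[1]
_STOPS = set(_TABLE.stop_codons)
_AA = dict(_TABLE.forward_table)
BASES = "ACGT"
SENSE_CODONS = sorted(_AA)


# ---------------------------------------------------------------- NG86 oracle
def oracle_sites(codon: str) -> tuple[float, float]:
    """Enumerate all 9 single-nt mutants; skip stops; thirds per position."""
    s = n = 0.0
    for pos in range(3):
        for base in BASES:
            if base == codon[pos]:
                continue
            mut = codon[:pos] + base + codon[pos + 1 :]
            if mut in _STOPS:
                continue
            if _AA[mut] == _AA[codon]:
                s += 1 / 3
            else:
                n += 1 / 3
    return s, n


def oracle_diffs(ca: str, cb: str) -> tuple[float, float]:
    """Average syn/nonsyn steps over all stop-free mutational orderings."""
    positions = [i for i in range(3) if ca[i] != cb[i]]
    if not positions:
        return 0.0, 0.0
    paths = []
    for order in itertools.permutations(positions):
        cur = ca
        path = []
        legal = True
        for p in order:
            nxt = cur[:p] + cb[p] + cur[p + 1 :]
            if nxt in _STOPS:
                legal = False
                break
            path.append((cur, nxt))
            cur = nxt
        if legal:
            paths.append(path)
    if not paths:
        raise ValueError("all pathways hit stops")
    sd = nd = 0.0
    for path in paths:
        for frm, to in path:
            if _AA[frm] == _AA[to]:
                sd += 1 / len(paths)
            else:
                nd += 1 / len(paths)
    return sd, nd


def oracle_kaks(codons_a: list[str], codons_b: list[str]) -> dict:
    """Naive NG86: site averaging over both sequences, JC correction."""
    S = N = Sd = Nd = 0.0
    for ca, cb in zip(codons_a, codons_b):
        try:
            sd, nd = oracle_diffs(ca, cb)
        except ValueError:
            continue
        sa, na = oracle_sites(ca)
        sb, nb = oracle_sites(cb)
        S += (sa + sb) / 2
        N += (na + nb) / 2
        Sd += sd
        Nd += nd
    pS, pN = Sd / S, Nd / N
    ks = -0.75 * math.log(1 - 4 * pS / 3)
    ka = -0.75 * math.log(1 - 4 * pN / 3)
    return {"S": S, "N": N, "Sd": Sd, "Nd": Nd, "pS": pS, "pN": pN, "Ks": ks, "Ka": ka}


def random_codon_pair_list(n_codons: int, rng: random.Random, max_diff: int = 2):
    """Random sense-codon pair lists with modest per-codon divergence."""
    cas, cbs = [], []
    for _ in range(n_codons):
        ca = rng.choice(SENSE_CODONS)
        cb = ca
        for _ in range(rng.randint(0, max_diff)):
            pos = rng.randrange(3)
            cb2 = cb[:pos] + rng.choice(BASES) + cb[pos + 1 :]
            if cb2 not in _STOPS:
                cb = cb2
        try:
            oracle_diffs(ca, cb)
        except ValueError:
            cb = ca
        cas.append(ca)
        cbs.append(cb)
    return cas, cbs


# ------------------------------------------------- affine alignment DP oracle
def affine_dp_score(a: str, b: str, matrix, gap_open: float, gap_extend: float) -> float:
    """Full three-state Gotoh DP; gap_open is the score of a gap's first
    position, gap_extend of each subsequent one (Biopython convention)."""
    NEG = -1e18
    n, m = len(a), len(b)
    M = [[NEG] * (m + 1) for _ in range(n + 1)]
    X = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in b (consume a)
    Y = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in a (consume b)
    M[0][0] = 0.0
    for i in range(n + 1):
        for j in range(m + 1):
            if i > 0 and j > 0:
                sub = matrix[a[i - 1], b[j - 1]]
                M[i][j] = max(M[i - 1][j - 1], X[i - 1][j - 1], Y[i - 1][j - 1]) + sub
            if i > 0:
                X[i][j] = max(
                    M[i - 1][j] + gap_open,
                    X[i - 1][j] + gap_extend,
                    Y[i - 1][j] + gap_open,
                )
            if j > 0:
                Y[i][j] = max(
                    M[i][j - 1] + gap_open,
                    Y[i][j - 1] + gap_extend,
                    X[i][j - 1] + gap_open,
                )
    return max(M[n][m], X[n][m], Y[n][m])


# --------------------------------------------------------- quartet / NJ oracle
def quartet_best_topology(ids, d) -> frozenset:
    """Least-squares best of the 3 unrooted quartet topologies.

    Returns the split {x, y} grouped together, via the four-point
    condition: the pairing with the smallest sum of cross distances.
    """
    a, b, c, e = ids
    sums = {
        frozenset((a, b)): d[(a, b)] + d[(c, e)],
        frozenset((a, c)): d[(a, c)] + d[(b, e)],
        frozenset((a, e)): d[(a, e)] + d[(b, c)],
    }
    return min(sums, key=sums.get)


def random_additive_tree(n_leaves: int, rng: random.Random):
    """Random binary unrooted tree; returns (splits, distance dict, ids).

    Built by sequential leaf attachment with strictly positive branch
    lengths; distances are path lengths (exactly additive).
    """
    # adjacency with edge lengths; nodes: leaves "L0..", internal negative ints
    ids = [f"L{i}" for i in range(n_leaves)]
    adj: dict = {}

    def connect(u, v, w):
        adj.setdefault(u, {})[v] = w
        adj.setdefault(v, {})[u] = w

    next_internal = [0]

    def new_internal():
        next_internal[0] -= 1
        return next_internal[0]

    # start with a 3-star
    center = new_internal()
    for leaf in ids[:3]:
        connect(center, leaf, rng.uniform(0.1, 1.0))
    for leaf in ids[3:]:
        # pick a random edge, subdivide, hang the new leaf
        u = rng.choice(list(adj))
        v = rng.choice(list(adj[u]))
        w = adj[u][v]
        mid = new_internal()
        cut = rng.uniform(0.2, 0.8) * w
        del adj[u][v]
        del adj[v][u]
        connect(u, mid, cut)
        connect(mid, v, w - cut)
        connect(mid, leaf, rng.uniform(0.1, 1.0))

    # path distances by BFS
    import collections

    d = {}
    for src in ids:
        dist = {src: 0.0}
        q = collections.deque([src])
        while q:
            x = q.popleft()
            for y, w in adj[x].items():
                if y not in dist:
                    dist[y] = dist[x] + w
                    q.append(y)
        for dst in ids:
            d[(src, dst)] = dist[dst]

    # splits: remove each internal edge, collect leaf side
    splits = set()
    ref = min(ids)
    internal_nodes = [x for x in adj if not isinstance(x, str)]
    for u in internal_nodes:
        for v in list(adj[u]):  # collect side of v when edge (u, v) is removed
            if isinstance(v, str):
                continue
            seen = {u}
            stack = [v]
            side = set()
            while stack:
                x = stack.pop()
                if x in seen:
                    continue
                seen.add(x)
                if isinstance(x, str):
                    side.add(x)
                else:
                    stack.extend(y for y in adj[x] if y not in seen)
            side = frozenset(side)
            if 1 < len(side) < n_leaves - 1:
                splits.add(side if ref not in side else frozenset(ids) - side)
    return splits, d, ids


# ------------------------------------------------------------- Fitch oracle
def fitch_exhaustive(parent_of: dict, leaf_states: dict, states: str) -> int:
    """Minimal changes over all internal-state assignments of a rooted tree.

    ``parent_of`` maps child -> parent over all nodes; the root has parent
    None. Leaves are the keys of ``leaf_states``.
    """
    nodes = set(parent_of) | {p for p in parent_of.values() if p is not None}
    internals = sorted(n for n in nodes if n not in leaf_states)
    best = math.inf
    for assignment in itertools.product(states, repeat=len(internals)):
        state = dict(zip(internals, assignment))
        state.update(leaf_states)
        changes = sum(
            1
            for child, parent in parent_of.items()
            if parent is not None and state[child] != state[parent]
        )
        best = min(best, changes)
    return best
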