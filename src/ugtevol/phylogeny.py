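"""Distance-based phylogenetics: neighbor-joining, bootstrap, Fitch scoring.

Trees are unrooted binary topologies represented with a trifurcating root
node (the final NJ join). Negative NJ branch-length estimates are clamped
to zero and flagged. Bootstrap support is the percentage of
column-resampled replicate trees containing each internal split of the
original tree.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "DistanceMatrix",
    "TreeNode",
    "Tree",
    "p_distance",
    "nj_tree",
    "bootstrap",
    "fitch_score",
]


@dataclass
class DistanceMatrix:
    """Symmetric nonnegative distances with a zero diagonal."""

    ids: list[str]
    d: np.ndarray

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=float)
        n = len(self.ids)
        if self.d.shape != (n, n):
            raise ValueError(f"matrix shape {self.d.shape} != ({n}, {n})")
        if not np.allclose(self.d, self.d.T):
            raise ValueError("distance matrix is not symmetric")
        if not np.allclose(np.diag(self.d), 0):
            raise ValueError("distance matrix diagonal is not zero")
        if not np.isfinite(self.d).all():
            raise ValueError("non-finite distances")

    def to_phylip(self) -> str:
        """PHYLIP square-format serialization."""
        out = io.StringIO()
        out.write(f"{len(self.ids)}\n")
        for name, row in zip(self.ids, self.d):
            out.write(f"{name:<10}" + "  ".join(f"{x:.6f}" for x in row) + "\n")
        return out.getvalue()


@dataclass
class TreeNode:
    name: str | None = None
    children: list[tuple["TreeNode", float]] = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list[str]:
        if self.is_leaf:
            return [self.name]
        out = []
        for child, _ in self.children:
            out.extend(child.leaves())
        return out


@dataclass
class Tree:
    """Unrooted tree (trifurcating root), optional per-split supports."""

    root: TreeNode
    negative_branches_clamped: int = 0
    supports: dict[frozenset, float] = field(default_factory=dict)

    def leaf_names(self) -> list[str]:
        return self.root.leaves()

    def splits(self) -> set[frozenset]:
        """Nontrivial bipartitions, each canonicalized as the side not
        containing the lexicographically smallest leaf."""
        all_leaves = frozenset(self.leaf_names())
        ref = min(all_leaves)
        out: set[frozenset] = set()

        def walk(node: TreeNode) -> frozenset:
            if node.is_leaf:
                return frozenset([node.name])
            below = frozenset()
            for child, _ in node.children:
                below |= walk(child)
            if 1 < len(below) < len(all_leaves) - 1:
                out.add(below if ref not in below else all_leaves - below)
            return below

        for child, _ in self.root.children:
            clade = walk(child)
            if 1 < len(clade) < len(all_leaves) - 1:
                out.add(clade if ref not in clade else all_leaves - clade)
        return out

    def newick(self, include_support: bool = True) -> str:
        all_leaves = frozenset(self.leaf_names())
        ref = min(all_leaves)

        def fmt(node: TreeNode, length: float | None) -> str:
            if node.is_leaf:
                body = node.name
            else:
                inner = ",".join(fmt(c, bl) for c, bl in node.children)
                label = ""
                if include_support and self.supports:
                    below = frozenset(node.leaves())
                    key = below if ref not in below else all_leaves - below
                    if key in self.supports:
                        label = f"{self.supports[key]:.0f}"
                body = f"({inner}){label}"
            return body if length is None else f"{body}:{length:.6f}"

        return fmt(self.root, None) + ";"

    @classmethod
    def from_newick(cls, text: str) -> "Tree":
        """Parse newick (internal-node labels read as split supports)."""
        import dendropy

        dtree = dendropy.Tree.get(data=text, schema="newick")

        def convert(dnode) -> TreeNode:
            if dnode.is_leaf():
                return TreeNode(name=dnode.taxon.label.replace(" ", "_"))
            node = TreeNode()
            for child in dnode.child_nodes():
                node.children.append(
                    (convert(child), child.edge.length if child.edge.length else 0.0)
                )
            return node

        tree = cls(root=convert(dtree.seed_node))

        # harvest internal labels as supports
        def harvest(dnode):
            for child in dnode.child_nodes():
                harvest(child)
            if not dnode.is_leaf() and dnode.label:
                leaves = frozenset(
                    lf.taxon.label.replace(" ", "_") for lf in dnode.leaf_iter()
                )
                all_leaves = frozenset(tree.leaf_names())
                ref = min(all_leaves)
                key = leaves if ref not in leaves else all_leaves - leaves
                try:
                    tree.supports[key] = float(dnode.label)
                except ValueError:
                    pass

        harvest(dtree.seed_node)
        return tree


def p_distance(alignment: dict[str, str]) -> DistanceMatrix:
    """Pairwise p-distances (1 - identity over shared non-gap columns).

    ``alignment`` maps ids to equal-length aligned sequences (e.g. the
    fixed-length PSPG windows, or pairwise-projected alignments padded to
    a common frame).
    """
    ids = list(alignment)
    if len({len(s) for s in alignment.values()}) != 1:
        raise ValueError("aligned sequences differ in length")
    n = len(ids)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            a, b = alignment[ids[i]], alignment[ids[j]]
            shared = [(x, y) for x, y in zip(a, b) if x != "-" and y != "-"]
            if not shared:
                raise ValueError(f"no shared columns between {ids[i]} and {ids[j]}")
            p = sum(x != y for x, y in shared) / len(shared)
            d[i, j] = d[j, i] = p
    return DistanceMatrix(ids, d)


def nj_tree(dm: DistanceMatrix) -> Tree:
    """Saitou-Nei neighbor joining with deterministic tie-breaking.

    The pair minimizing the Q-criterion is joined at each step, ties
    broken by the smallest (i, j) index pair in current node order; final
    three nodes are joined at a trifurcating root. Negative branch-length
    estimates are clamped to zero and counted. Exactly additive matrices
    are recovered with their generating topology.
    """
    n = len(dm.ids)
    if n < 3:
        raise ValueError("neighbor joining requires at least 3 taxa")
    nodes: list[TreeNode] = [TreeNode(name=i) for i in dm.ids]
    D = dm.d.copy()
    clamped = 0

    def clamp(x: float) -> float:
        nonlocal clamped
        if x < 0:
            clamped += 1
            return 0.0
        return x

    while len(nodes) > 3:
        m = len(nodes)
        r = D.sum(axis=1)
        Q = (m - 2) * D - r[:, None] - r[None, :]
        np.fill_diagonal(Q, np.inf)
        # smallest Q; ties -> smallest (i, j), i < j, row-major scan
        best = (np.inf, -1, -1)
        for i in range(m):
            for j in range(i + 1, m):
                if Q[i, j] < best[0] - 1e-12:
                    best = (Q[i, j], i, j)
        _, i, j = best
        li = clamp(D[i, j] / 2 + (r[i] - r[j]) / (2 * (m - 2)))
        lj = clamp(D[i, j] - (D[i, j] / 2 + (r[i] - r[j]) / (2 * (m - 2))))
        new = TreeNode(children=[(nodes[i], li), (nodes[j], lj)])
        du = 0.5 * (D[i, :] + D[j, :] - D[i, j])
        keep = [k for k in range(m) if k not in (i, j)]
        D2 = np.zeros((m - 1, m - 1))
        D2[:-1, :-1] = D[np.ix_(keep, keep)]
        D2[-1, :-1] = D2[:-1, -1] = du[keep]
        D = D2
        nodes = [nodes[k] for k in keep] + [new]

    d01, d02, d12 = D[0, 1], D[0, 2], D[1, 2]
    l0 = clamp((d01 + d02 - d12) / 2)
    l1 = clamp((d01 + d12 - d02) / 2)
    l2 = clamp((d02 + d12 - d01) / 2)
    root = TreeNode(children=[(nodes[0], l0), (nodes[1], l1), (nodes[2], l2)])
    return Tree(root=root, negative_branches_clamped=clamped)


def bootstrap(
    alignment: dict[str, str], n_reps: int = 500, seed: int = 0
) -> dict[frozenset, float]:
    """Per-split bootstrap support for the NJ tree of ``alignment``.

    Columns are resampled with replacement ``n_reps`` times; support for
    each split of the original tree is the percentage of replicate NJ
    trees containing it. Seeded and reproducible; invariant to leaf order.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    ids = sorted(alignment)
    lengths = {len(s) for s in alignment.values()}
    if lengths == {0} or not alignment:
        raise ValueError("empty alignment")
    cols = np.array([list(alignment[i]) for i in ids]).T  # (n_cols, n_taxa)
    n_cols = cols.shape[0]

    original = nj_tree(p_distance({i: alignment[i] for i in ids}))
    targets = original.splits()
    counts = {s: 0 for s in targets}

    rng = np.random.default_rng(seed)
    for _ in range(n_reps):
        idx = rng.integers(0, n_cols, size=n_cols)
        resampled = {i: "".join(cols[idx, k]) for k, i in enumerate(ids)}
        rep_splits = nj_tree(p_distance(resampled)).splits()
        for s in targets:
            if s in rep_splits:
                counts[s] += 1
    return {s: 100.0 * c / n_reps for s, c in counts.items()}


def _fitch_column(tree: Tree, states: dict[str, str]) -> int:
    """Fitch minimal state changes for one character column.

    The unrooted tree is rooted on the edge to an arbitrary leaf, making
    every internal node binary, then the classic set intersection/union
    pass counts the changes.
    """
    adj: dict[int, list[TreeNode]] = {}

    def build(node: TreeNode, parent: TreeNode | None):
        adj.setdefault(id(node), [])
        if parent is not None:
            adj[id(node)].append(parent)
        for child, _ in node.children:
            adj[id(node)].append(child)
            build(child, node)

    build(tree.root, None)

    # find a leaf to root on
    start = tree.root
    while not start.is_leaf:
        start = start.children[0][0]

    changes = 0

    def down(node: TreeNode, parent: TreeNode) -> set:
        nonlocal changes
        kids = [x for x in adj[id(node)] if x is not parent]
        if not kids:
            return {states[node.name]}
        current: set | None = None
        for k in kids:
            s = down(k, node)
            if current is None:
                current = s
            else:
                inter = current & s
                if inter:
                    current = inter
                else:
                    current = current | s
                    changes += 1
        return current

    neighbor = adj[id(start)][0]
    below = down(neighbor, start)
    if states[start.name] not in below:
        changes += 1
    return changes


def fitch_score(tree: Tree, alignment: dict[str, str]) -> int:
    """Parsimony length: sum of per-column Fitch minimal change counts."""
    leaves = set(tree.leaf_names())
    if leaves != set(alignment):
        raise ValueError("tree leaves do not match alignment ids")
    if len({len(s) for s in alignment.values()}) != 1:
        raise ValueError("aligned sequences differ in length")
    n_cols = len(next(iter(alignment.values())))
    total = 0
    for c in range(n_cols):
        total += _fitch_column(tree, {i: s[c] for i, s in alignment.items()})
    return total
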