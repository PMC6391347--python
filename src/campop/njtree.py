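"""Unrooted neighbor-joining trees with locus-resampling bootstrap support.

Classical saitou–nei NJ: at each step join the pair of active nodes
minimizing the Q criterion, estimate the two new branch lengths, and reduce
the distance matrix. On an additive distance matrix the generating tree
(topology and branch lengths) is recovered exactly. Trees are unrooted;
support values attach to bipartitions (internal edges), computed by
resampling loci with replacement and recomputing the distances and the tree.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import GenotypeMatrix
from .distances import DistanceMatrix, individual_distances


@dataclass
class Tree:
    """Unrooted tree as an undirected adjacency structure.

    Leaves are labelled nodes; internal nodes are anonymous integers.
    ``support`` maps internal edges (as node pairs) to bootstrap percentages.
    """

    adjacency: dict[object, dict[object, float]] = field(default_factory=dict)
    leaves: list[str] = field(default_factory=list)
    support: dict[frozenset, float] = field(default_factory=dict)

    def add_edge(self, a, b, length: float) -> None:
        self.adjacency.setdefault(a, {})[b] = length
        self.adjacency.setdefault(b, {})[a] = length

    @property
    def n_leaves(self) -> int:
        return len(self.leaves)

    def edges(self) -> list[tuple[object, object, float]]:
        seen = set()
        out = []
        for a, nbrs in self.adjacency.items():
            for b, length in nbrs.items():
                key = frozenset((a, b))
                if key not in seen:
                    seen.add(key)
                    out.append((a, b, length))
        return out

    def bipartitions(self) -> set[frozenset]:
        """Non-trivial splits (both sides ≥ 2 leaves), as the smaller side.

        Each internal edge of an unrooted tree induces one bipartition of the
        leaf set; the canonical representative is the lexicographically
        smaller frozenset (by sorted leaf tuple) of the two sides.
        """
        leafset = set(self.leaves)
        splits = set()
        for a, b, _ in self.edges():
            side = self._leaves_behind(a, b)
            other = leafset - side
            if len(side) < 2 or len(other) < 2:
                continue
            splits.add(self._canonical(side))
        return splits

    def _canonical(self, side: set) -> frozenset:
        other = set(self.leaves) - side
        return frozenset(min(sorted(side), sorted(other)))

    def _leaves_behind(self, away_from, start) -> set:
        """Leaves reachable from ``start`` without crossing ``away_from``."""
        stack = [start]
        visited = {away_from, start}
        found = set()
        leafset = set(self.leaves)
        while stack:
            node = stack.pop()
            if node in leafset:
                found.add(node)
            for nbr in self.adjacency[node]:
                if nbr not in visited:
                    visited.add(nbr)
                    stack.append(nbr)
        return found

    def edge_for_bipartition(self, split: frozenset):
        for a, b, _ in self.edges():
            side = self._leaves_behind(a, b)
            if len(side) < 2 or len(set(self.leaves) - side) < 2:
                continue
            if self._canonical(side) == split:
                return (a, b)
        return None

    def to_newick(self, include_support: bool = True) -> str:
        """Newick string with branch lengths and optional support labels.

        The tree is written rooted at an arbitrary internal node (or the
        first leaf for 2-taxon trees); the underlying tree is unrooted.
        """
        internal = [n for n in self.adjacency if n not in set(self.leaves)]
        if not internal:  # 2-taxon tree: single edge
            a, b, length = self.edges()[0]
            return f"({a}:0,{b}:{length:.6g});"
        root = internal[0]

        def render(node, parent) -> str:
            children = [n for n in self.adjacency[node] if n != parent]
            if not children:
                length = self.adjacency[parent][node]
                return f"{node}:{length:.6g}"
            parts = ",".join(render(c, node) for c in children)
            if parent is None:
                return f"({parts})"
            length = self.adjacency[parent][node]
            label = ""
            if include_support:
                sup = self.support.get(frozenset((node, parent)))
                if sup is not None:
                    label = f"{sup:g}"
            return f"({parts}){label}:{length:.6g}"

        return render(root, None) + ";"


def _tiebreak_key(reps: dict, i, j) -> tuple:
    a, b = sorted((reps[i], reps[j]))
    return (a, b)


def neighbor_joining(distances: DistanceMatrix) -> Tree:
    """Classical neighbor joining of a symmetric distance matrix.

    Deterministic: Q-criterion ties are broken by the lexicographically
    smallest pair of representative leaf labels (the smallest leaf under each
    active node). Negative branch-length estimates are floored at zero with
    the excess transferred to the sibling branch, preserving their sum.
    """
    n = distances.n
    if n < 2:
        raise ValueError("need at least 2 entities")
    tree = Tree(leaves=list(distances.labels))
    if n == 2:
        tree.add_edge(distances.labels[0], distances.labels[1],
                      float(distances.d[0, 1]))
        return tree

    active: list[object] = list(distances.labels)
    reps = {lab: lab for lab in active}  # smallest leaf label per active node
    d = {a: {} for a in active}
    for i, a in enumerate(active):
        for j, b in enumerate(active):
            if i != j:
                d[a][b] = float(distances.d[i, j])

    next_internal = 0
    while len(active) > 2:
        r = len(active)
        totals = {a: sum(d[a][b] for b in active if b != a) for a in active}
        best = None
        for i in range(r):
            for j in range(i + 1, r):
                a, b = active[i], active[j]
                qv = (r - 2) * d[a][b] - totals[a] - totals[b]
                key = (qv, _tiebreak_key(reps, a, b))
                if best is None or key < best[0]:
                    best = (key, a, b)
        _, a, b = best
        la = 0.5 * d[a][b] + (totals[a] - totals[b]) / (2.0 * (r - 2))
        lb = d[a][b] - la
        # floor-and-transfer: negative estimate moved to the sibling branch
        if la < 0:
            lb += la
            la = 0.0
        if lb < 0:
            la += lb
            lb = 0.0
        node = f"__internal{next_internal}"
        next_internal += 1
        tree.add_edge(node, a, max(la, 0.0))
        tree.add_edge(node, b, max(lb, 0.0))
        new_d = {}
        for c in active:
            if c in (a, b):
                continue
            new_d[c] = 0.5 * (d[a][c] + d[b][c] - d[a][b])
        active = [c for c in active if c not in (a, b)] + [node]
        reps[node] = min(reps[a], reps[b])
        d[node] = {}
        for c, dist in new_d.items():
            d[node][c] = dist
            d[c][node] = dist

    a, b = active
    tree.add_edge(a, b, max(float(d[a][b]), 0.0))
    return tree


def bootstrap_support(
    genotypes: GenotypeMatrix,
    n_replicates: int = 100,
    seed: int | None = None,
    distance_fn=individual_distances,
) -> Tree:
    """NJ tree with bipartition bootstrap support from locus resampling.

    Loci are resampled with replacement ``n_replicates`` times; distances and
    the NJ tree are recomputed per replicate, and each internal edge of the
    full-data tree is annotated with the percentage of replicates whose tree
    contains the same bipartition. Deterministic under ``seed``.
    """
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    if genotypes.n_loci == 1:
        import warnings

        warnings.warn("single-locus bootstrap carries no information",
                      stacklevel=2)
    rng = np.random.default_rng(seed)
    base = neighbor_joining(distance_fn(genotypes))
    targets = base.bipartitions()
    counts = {split: 0 for split in targets}
    for _ in range(n_replicates):
        idx = rng.integers(0, genotypes.n_loci, size=genotypes.n_loci)
        resampled = GenotypeMatrix(
            genotypes.dosages[:, idx],
            genotypes.sample_ids,
            [f"b{i}" for i in range(genotypes.n_loci)],
        )
        rep_tree = neighbor_joining(distance_fn(resampled))
        rep_splits = rep_tree.bipartitions()
        for split in targets:
            if split in rep_splits:
                counts[split] += 1
    for split, c in counts.items():
        edge = base.edge_for_bipartition(split)
        if edge is not None:
            base.support[frozenset(edge)] = 100.0 * c / n_replicates
    return base


def bipartition_table(tree: Tree):
    """Delimited-friendly table of internal-edge bipartitions and supports."""
    import pandas as pd

    rows = []
    for split in sorted(tree.bipartitions(), key=lambda s: sorted(s)):
        edge = tree.edge_for_bipartition(split)
        sup = tree.support.get(frozenset(edge)) if edge else None
        rows.append(
            {"bipartition": "|".join(sorted(split)), "support": sup}
        )
    return pd.DataFrame(rows)
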