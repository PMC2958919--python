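"""Distances, trees and split networks from dominant-marker matrices.

The chain implemented here is the classical multilocus-marker route:
Jaccard distances between band-presence profiles (shared absences carry no
information for dominant markers and are excluded by construction),
neighbor-joining trees with column-bootstrap support, and neighbor-net
split networks (circular split systems with non-negative least-squares
weights).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import dendropy
import numpy as np
from scipy.optimize import nnls

from .io_formats import AFLPMatrix

__all__ = [
    "DistanceMatrix",
    "SupportTree",
    "SplitSystem",
    "jaccard_matrix",
    "nj_tree",
    "bootstrap_support",
    "neighbor_net",
    "circular_split_weights",
    "tree_bipartitions",
    "write_phylip_distances",
]


@dataclass
class DistanceMatrix:
    """Symmetric non-negative distance matrix with zero diagonal."""

    ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        d = np.asarray(self.values, dtype=float)
        if d.shape != (len(self.ids), len(self.ids)):
            raise ValueError("distance matrix shape inconsistent with ids")
        if not np.allclose(d, d.T, atol=1e-12):
            raise ValueError("distance matrix must be symmetric")
        if (np.diag(d) != 0).any():
            raise ValueError("distance matrix diagonal must be zero")
        if (d < 0).any():
            raise ValueError("distances must be non-negative")
        self.values = d

    @property
    def n(self) -> int:
        return len(self.ids)


@dataclass
class SupportTree:
    """Unrooted branch-length tree with optional per-edge bootstrap support.

    ``supports`` maps a non-trivial bipartition — the frozenset of tip labels
    on the side not containing the reference (first) taxon — to a percentage
    in [0, 100].
    """

    tree: dendropy.Tree
    supports: dict[frozenset, float] | None = None

    def __post_init__(self) -> None:
        if self.supports is not None:
            for split, s in self.supports.items():
                if not 0.0 <= s <= 100.0:
                    raise ValueError(f"support {s} for {set(split)} outside [0, 100]")

    def tip_labels(self) -> list[str]:
        return [leaf.taxon.label for leaf in self.tree.leaf_node_iter()]

    def newick(self) -> str:
        """Newick string; bootstrap supports become internal node labels."""
        if self.supports is not None:
            ref = min(self.tip_labels())
            for node in self.tree.preorder_internal_node_iter():
                side = frozenset(l.taxon.label for l in node.leaf_iter())
                if ref in side:
                    side = frozenset(self.tip_labels()) - side
                if side in self.supports:
                    node.label = f"{self.supports[side]:g}"
        return self.tree.as_string(
            schema="newick", suppress_rooting=True, unquoted_underscores=True
        ).strip()


@dataclass
class SplitSystem:
    """Weighted circular split system: every split is an interval of the
    circular taxon ordering."""

    ordering: list[str]
    splits: list[tuple[frozenset, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        pos = {t: i for i, t in enumerate(self.ordering)}
        n = len(self.ordering)
        for side, w in self.splits:
            if w <= 0:
                raise ValueError("split weights must be positive")
            if not self._is_interval(sorted(pos[t] for t in side), n):
                raise ValueError(f"split {sorted(side)} is not circular")

    @staticmethod
    def _is_interval(idx: list[int], n: int) -> bool:
        if not idx or len(idx) == n:
            return False
        if idx[-1] - idx[0] == len(idx) - 1:
            return True
        # may wrap: complement must then be contiguous
        comp = sorted(set(range(n)) - set(idx))
        return comp[-1] - comp[0] == len(comp) - 1

    def nontrivial(self) -> list[tuple[frozenset, float]]:
        n = len(self.ordering)
        return [(s, w) for s, w in self.splits if 1 < len(s) < n - 1]

    def induced_distances(self) -> DistanceMatrix:
        """Metric implied by the splits: d(x,y) = total weight separating x, y."""
        n = len(self.ordering)
        pos = {t: i for i, t in enumerate(self.ordering)}
        d = np.zeros((n, n))
        for side, w in self.splits:
            mask = np.zeros(n, dtype=bool)
            for t in side:
                mask[pos[t]] = True
            sep = mask[:, None] != mask[None, :]
            d[sep] += w
        return DistanceMatrix(list(self.ordering), d)

    def as_nexus(self) -> str:
        """NEXUS text with a SplitsTree-compatible Splits block."""
        n = len(self.ordering)
        lines = [
            "#NEXUS",
            "BEGIN Taxa;",
            f"DIMENSIONS ntax={n};",
            "TAXLABELS",
        ]
        lines += [f"[{i + 1}] '{t}'" for i, t in enumerate(self.ordering)]
        lines += [
            ";",
            "END;",
            "BEGIN Splits;",
            f"DIMENSIONS ntax={n} nsplits={len(self.splits)};",
            "FORMAT labels=no weights=yes confidences=no intervals=no;",
            "CYCLE " + " ".join(str(i + 1) for i in range(n)) + ";",
            "MATRIX",
        ]
        pos = {t: i + 1 for i, t in enumerate(self.ordering)}
        for k, (side, w) in enumerate(self.splits):
            members = " ".join(str(pos[t]) for t in sorted(side, key=lambda t: pos[t]))
            lines.append(f"[{k + 1}] {w:.10g} {members},")
        lines += [";", "END;"]
        return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# Jaccard distances
# ---------------------------------------------------------------------------

def jaccard_matrix(m: AFLPMatrix) -> DistanceMatrix:
    """Jaccard distances between dominant-marker profiles.

    d = 1 − a / (a + b + c) with a = shared presences and b, c the presences
    unique to either specimen, computed per pair over markers that are
    non-missing in both (pairwise deletion).  Shared absences do not enter:
    absence of a dominant band is uninformative about homology.
    """
    present = m.present().astype(np.int64)
    valid = (~m.missing()).astype(np.int64)
    a = present @ present.T
    b = present @ (valid - present).T
    c = b.T
    union = a + b + c
    off = ~np.eye(m.n_specimens, dtype=bool)
    bad = (union == 0) & off
    if bad.any():
        i, j = np.argwhere(bad)[0]
        raise ValueError(
            f"specimens {m.specimen_ids[i]!r} and {m.specimen_ids[j]!r} share no "
            "present bands over mutually scored markers; Jaccard undefined"
        )
    with np.errstate(invalid="ignore"):
        d = 1.0 - a / np.where(union == 0, 1, union)
    np.fill_diagonal(d, 0.0)
    d = (d + d.T) / 2.0  # exact symmetry despite float rounding
    return DistanceMatrix(list(m.specimen_ids), d)


# ---------------------------------------------------------------------------
# Neighbor joining
# ---------------------------------------------------------------------------

def nj_tree(d: DistanceMatrix) -> SupportTree:
    """Saitou–Nei neighbor joining with the standard Q-criterion.

    Deterministic: ties in Q are broken toward the lexicographically lowest
    index pair.  Negative branch lengths are clamped to zero with the deficit
    transferred to the sibling edge (Kuhner–Felsenstein convention).
    """
    n = d.n
    if n < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")
    taxa = dendropy.TaxonNamespace(d.ids)
    tree = dendropy.Tree(taxon_namespace=taxa)
    nodes: list[dendropy.Node] = []
    for label in d.ids:
        node = dendropy.Node(taxon=taxa.get_taxon(label))
        nodes.append(node)
    D = d.values.copy()
    active = list(range(n))

    def _join(i_pos: int, j_pos: int, li: float, lj: float) -> dendropy.Node:
        u = dendropy.Node()
        ni, nj = nodes[active[i_pos]], nodes[active[j_pos]]
        # clamp negatives, moving the deficit to the sibling edge
        if li < 0:
            lj += li
            li = 0.0
        if lj < 0:
            li += lj
            lj = 0.0
        u.add_child(ni)
        ni.edge.length = max(li, 0.0)
        u.add_child(nj)
        nj.edge.length = max(lj, 0.0)
        return u

    while len(active) > 3:
        r = len(active)
        sub = D[np.ix_(active, active)]
        rowsum = sub.sum(axis=1)
        Q = (r - 2) * sub - rowsum[:, None] - rowsum[None, :]
        # upper triangle only; flat argmin scans row-major, so exact ties
        # resolve to the lexicographically lowest index pair
        Q[np.tril_indices(r)] = np.inf
        bi, bj = np.unravel_index(int(np.argmin(Q)), Q.shape)
        li = 0.5 * sub[bi, bj] + (rowsum[bi] - rowsum[bj]) / (2.0 * (r - 2))
        lj = sub[bi, bj] - li
        u = _join(bi, bj, li, lj)
        gi, gj = active[bi], active[bj]
        du = 0.5 * (D[gi, :] + D[gj, :] - D[gi, gj])
        D = np.vstack([D, du])
        D = np.column_stack([D, np.append(du, 0.0)])
        nodes.append(u)
        active = [g for g in active if g not in (gi, gj)] + [len(nodes) - 1]

    # final three-point join
    (ga, gb, gc) = active
    dab, dac, dbc = D[ga, gb], D[ga, gc], D[gb, gc]
    la = 0.5 * (dab + dac - dbc)
    lb = 0.5 * (dab + dbc - dac)
    lc = 0.5 * (dac + dbc - dab)
    centre = dendropy.Node()
    for g, length in ((ga, la), (gb, lb), (gc, lc)):
        centre.add_child(nodes[g])
        nodes[g].edge.length = max(length, 0.0)
    tree.seed_node = centre
    tree.is_rooted = False
    return SupportTree(tree)


def tree_bipartitions(tree: dendropy.Tree) -> set[frozenset]:
    """Non-trivial bipartitions of an unrooted tree, each as the frozenset of
    tip labels on the side not containing the lexicographically first tip."""
    labels = sorted(leaf.taxon.label for leaf in tree.leaf_node_iter())
    all_tips = frozenset(labels)
    ref = labels[0]
    out: set[frozenset] = set()
    for node in tree.preorder_internal_node_iter():
        side = frozenset(l.taxon.label for l in node.leaf_iter())
        if ref in side:
            side = all_tips - side
        if 1 < len(side) < len(labels) - 1:
            out.add(side)
    return out


def bootstrap_support(m: AFLPMatrix, replicates: int = 1000, seed: int = 0) -> SupportTree:
    """Column-bootstrap support for the NJ tree of the Jaccard distances.

    Markers are the exchangeable units: columns are resampled with
    replacement, specimens kept fixed.  Support of an edge of the
    point-estimate tree is the percentage of replicate NJ trees containing
    the same bipartition.
    """
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    point = nj_tree(jaccard_matrix(m))
    target = tree_bipartitions(point.tree)
    counts = {split: 0 for split in target}
    rng = np.random.default_rng(seed)
    for _ in range(replicates):
        cols = rng.integers(0, m.n_markers, size=m.n_markers)
        rep = AFLPMatrix(
            list(m.specimen_ids),
            [f"b{j}" for j in range(m.n_markers)],
            m.values[:, cols],
        )
        rep_tree = nj_tree(jaccard_matrix(rep))
        found = tree_bipartitions(rep_tree.tree)
        for split in target:
            if split in found:
                counts[split] += 1
    supports = {s: 100.0 * c / replicates for s, c in counts.items()}
    return SupportTree(point.tree, supports)


# ---------------------------------------------------------------------------
# Neighbor-net
# ---------------------------------------------------------------------------

def _neighbor_net_ordering(D0: np.ndarray) -> list[int]:
    """Circular ordering by the two-stage agglomerative selection scheme.

    Nodes live in chain components of size one or two; cluster pairs are
    chosen by the neighbor-joining Q-criterion on averaged cluster distances,
    then endpoint nodes by the analogous node-level criterion; chains longer
    than two are immediately reduced three-into-two, and the reductions are
    expanded in reverse at the end to yield the circular ordering.
    """
    n0 = D0.shape[0]
    if n0 <= 3:
        return list(range(n0))
    D = [list(row) for row in D0]          # grows as reduced nodes are added
    clusters: list[list[int]] = [[i] for i in range(n0)]
    expansions: list[tuple[int, int, tuple[int, int, int]]] = []
    next_id = n0

    def dist(x: int, y: int) -> float:
        return D[x][y]

    def add_node(drow: dict[int, float]) -> int:
        nonlocal next_id
        idx = next_id
        next_id += 1
        for row in D:
            row.append(0.0)
        new_row = [0.0] * (len(D) + 1)
        for j, v in drow.items():
            new_row[j] = v
            D[j][idx] = v
        D.append(new_row)
        return idx

    def reduce3(x: int, y: int, z: int, others: list[int]) -> tuple[int, int]:
        """Replace chain x-y-z by u-v; record the expansion."""
        du = {w: (2.0 / 3.0) * dist(x, w) + (1.0 / 3.0) * dist(y, w) for w in others}
        dv = {w: (2.0 / 3.0) * dist(z, w) + (1.0 / 3.0) * dist(y, w) for w in others}
        duv = (dist(x, y) + dist(x, z) + dist(y, z)) / 3.0
        u = add_node(du)
        v = add_node({**dv, u: duv})
        expansions.append((u, v, (x, y, z)))
        return u, v

    while sum(len(c) for c in clusters) > 3 and len(clusters) > 1:
        N = len(clusters)
        # averaged distances between clusters
        cd = np.zeros((N, N))
        for a in range(N):
            for b in range(a + 1, N):
                vals = [dist(x, y) for x in clusters[a] for y in clusters[b]]
                cd[a, b] = cd[b, a] = float(np.mean(vals))
        if N > 2:
            rs = cd.sum(axis=1)
            best, pa, pb = np.inf, 0, 1
            for a in range(N):
                for b in range(a + 1, N):
                    qab = (N - 2) * cd[a, b] - rs[a] - rs[b]
                    if qab < best - 1e-15:
                        best, pa, pb = qab, a, b
        else:
            pa, pb = 0, 1
        C1, C2 = clusters[pa], clusters[pb]
        other_clusters = [clusters[c] for c in range(N) if c not in (pa, pb)]
        # endpoint-node selection within the chosen cluster pair
        m = N + len(C1) + len(C2) - 2
        cand_x = [C1[0]] if len(C1) == 1 else [C1[0], C1[-1]]
        cand_y = [C2[0]] if len(C2) == 1 else [C2[0], C2[-1]]

        def node_sum(x: int, own_pair: tuple[int, ...]) -> float:
            s = 0.0
            for C in other_clusters:
                s += float(np.mean([dist(x, z) for z in C]))
            for z in C1 + C2:
                if z != x:
                    s += dist(x, z)
            return s

        best, bx, by = np.inf, cand_x[0], cand_y[0]
        for x in cand_x:
            for y in cand_y:
                q = (m - 2) * dist(x, y) - node_sum(x, ()) - node_sum(y, ())
                if q < best - 1e-15:
                    best, bx, by = q, x, y
        # orient the chains so ... - x  links to  y - ...
        chain1 = C1 if C1[-1] == bx else list(reversed(C1))
        chain2 = C2 if C2[0] == by else list(reversed(C2))
        merged = chain1 + chain2
        others_flat = [z for C in other_clusters for z in C]
        while len(merged) > 2:
            rest = others_flat + merged[3:]
            u, v = reduce3(merged[0], merged[1], merged[2], rest)
            merged = [u, v] + merged[3:]
        clusters = [merged] + other_clusters

    # close the remaining <=3 nodes into a cycle, preserving chain adjacency
    cycle: list[int] = [z for C in clusters for z in C]
    # expand reductions in reverse
    for u, v, (x, y, z) in reversed(expansions):
        iu, iv = cycle.index(u), cycle.index(v)
        if (iu + 1) % len(cycle) == iv:
            cycle[iu:iu + 1] = [x, y]
            cycle[cycle.index(v)] = z
        elif (iv + 1) % len(cycle) == iu:
            cycle[iv:iv + 1] = [z, y]
            cycle[cycle.index(u)] = x
        else:  # u, v not adjacent: should not happen, fall back conservatively
            cycle[iu] = x
            cycle[iv] = z
            cycle.insert(iu + 1, y)
    return cycle


def circular_split_weights(
    d: DistanceMatrix, ordering: Sequence[int], eps_fraction: float = 1e-8
) -> list[tuple[frozenset, float]]:
    """Non-negative least-squares split weights for a fixed circular ordering.

    All n(n−1)/2 splits compatible with the ordering are candidate predictors;
    each pairwise distance is modelled as the sum of the weights of the splits
    separating the pair.  Splits whose weight falls at or below
    ``eps_fraction`` of the total weight are dropped (numerical floor of the
    active-set solver).
    """
    n = d.n
    order = list(ordering)
    splits = []  # as index intervals [i..j] over order positions 1..n-1
    for i in range(1, n):
        for j in range(i, n):
            splits.append((i, j))
    pairs = [(a, b) for a in range(n) for b in range(a + 1, n)]
    pos = np.empty(n, dtype=int)
    for rank, taxon_idx in enumerate(order):
        pos[taxon_idx] = rank
    A = np.zeros((len(pairs), len(splits)))
    for col, (i, j) in enumerate(splits):
        member = np.zeros(n, dtype=bool)
        member[i:j + 1] = True
        for row, (a, b) in enumerate(pairs):
            if member[pos[a]] != member[pos[b]]:
                A[row, col] = 1.0
    y = np.array([d.values[a, b] for a, b in pairs])
    w, _ = nnls(A, y)
    total = w.sum()
    floor = eps_fraction * total if total > 0 else 0.0
    out = []
    for col, (i, j) in enumerate(splits):
        if w[col] > floor:
            side = frozenset(d.ids[order[k]] for k in range(i, j + 1))
            out.append((side, float(w[col])))
    return out


def neighbor_net(d: DistanceMatrix, eps_fraction: float = 1e-8) -> SplitSystem:
    """Neighbor-net split network: agglomerative circular ordering followed by
    non-negative least-squares estimation of circular split weights."""
    order = _neighbor_net_ordering(d.values)
    splits = circular_split_weights(d, order, eps_fraction)
    return SplitSystem([d.ids[i] for i in order], splits)


# ---------------------------------------------------------------------------
# Exports
# ---------------------------------------------------------------------------

def write_phylip_distances(d: DistanceMatrix, path: str | Path | None = None) -> str:
    """Square PHYLIP distance-matrix text."""
    lines = [f"    {d.n}"]
    for i, name in enumerate(d.ids):
        row = " ".join(f"{v:.6f}" for v in d.values[i])
        lines.append(f"{name[:10]:<10} {row}")
    text = "\n".join(lines) + "\n"
    if path is not None:
        Path(path).write_text(text)
    return text
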