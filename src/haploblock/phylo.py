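"""Segment-partitioned phylogenetics for gene-conversion inference.

For each gene segment (exons 1–3, introns 1–2, the 5' part of intron 3 and
the 3' region) a Tamura (1992) three-parameter distance matrix is computed
from the alignment, a neighbor-joining tree is built, and Robinson–Foulds
distances between segment trees quantify incongruence.  Adjacent segments
whose trees disagree mark candidate gene-conversion breakpoints.

The T92 distance corrects for transition/transversion bias and GC content:

    d = -h ln(1 - P/h - Q) - (1/2)(1 - h) ln(1 - 2Q),   h = 2 theta (1 - theta)

with theta the GC fraction, P the transition proportion and Q the
transversion proportion over valid (gap- and N-free) columns.
"""

from __future__ import annotations

import itertools
import math
import sys
from dataclasses import dataclass, field

import numpy as np

PURINES = {"A", "G"}
PYRIMIDINES = {"C", "T"}
GC = {"G", "C"}


class SaturationError(ValueError):
    """Distance undefined: substitution saturation for a pair."""


@dataclass
class T92Params:
    theta: float
    P: float
    Q: float

    @property
    def h(self) -> float:
        return 2.0 * self.theta * (1.0 - self.theta)


def _pair_counts(a: str, b: str) -> tuple[int, int, int, float]:
    """(transitions, transversions, valid columns, mean GC) for an aligned pair."""
    ts = tv = valid = gc = 0
    for ca, cb in zip(a, b):
        if ca in "-N" or cb in "-N":
            continue
        valid += 1
        gc += (ca in GC) + (cb in GC)
        if ca == cb:
            continue
        if (ca in PURINES) == (cb in PURINES):
            ts += 1
        else:
            tv += 1
    return ts, tv, valid, (gc / (2 * valid) if valid else float("nan"))


def t92_params(a: str, b: str) -> T92Params:
    if len(a) != len(b):
        raise ValueError("aligned sequences must have equal length")
    ts, tv, valid, theta = _pair_counts(a, b)
    if valid == 0:
        raise ValueError("no valid columns for distance estimation")
    return T92Params(theta=theta, P=ts / valid, Q=tv / valid)


def t92_distance(a: str, b: str, theta: float | None = None) -> float:
    """Tamura three-parameter distance between two aligned sequences.

    Columns with a gap or N in either sequence are excluded (pairwise
    deletion).  ``theta`` defaults to the mean GC fraction of the pair over
    the included columns; pass a value to use an alignment-wide estimate.
    """
    p = t92_params(a, b)
    if p.P == 0 and p.Q == 0:
        return 0.0
    th = p.theta if theta is None else theta
    h = 2.0 * th * (1.0 - th)
    if h == 0:
        # no GC heterozygosity: transitions carry no information in the model
        h = 1e-12
    arg1 = 1.0 - p.P / h - p.Q
    arg2 = 1.0 - 2.0 * p.Q
    if arg1 <= 0 or arg2 <= 0:
        raise SaturationError(f"saturated pair (P={p.P:.3f}, Q={p.Q:.3f}, theta={th:.3f})")
    return -h * math.log(arg1) - 0.5 * (1.0 - h) * math.log(arg2)


@dataclass
class DistanceMatrix:
    taxa: list[str]
    d: np.ndarray

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=float)
        n = len(self.taxa)
        if self.d.shape != (n, n):
            raise ValueError("matrix shape does not match taxa")
        if not np.allclose(self.d, self.d.T):
            raise ValueError("distance matrix must be symmetric")
        if (self.d < 0).any():
            raise ValueError("distances must be non-negative")

    @classmethod
    def from_alignment(cls, names: list[str], rows: list[str], theta: float | None = None):
        n = len(names)
        d = np.zeros((n, n))
        for i, j in itertools.combinations(range(n), 2):
            d[i, j] = d[j, i] = t92_distance(rows[i], rows[j], theta=theta)
        return cls(taxa=list(names), d=d)


class Node:
    __slots__ = ("name", "children", "length")

    def __init__(self, name: str = "", length: float = 0.0):
        self.name = name
        self.children: list[Node] = []
        self.length = length

    def is_leaf(self) -> bool:
        return not self.children


class Tree:
    """Unrooted tree stored with an arbitrary internal root (degree >= 3)."""

    def __init__(self, root: Node):
        self.root = root

    def leaves(self) -> list[Node]:
        out = []

        def walk(n: Node) -> None:
            if n.is_leaf():
                out.append(n)
            for c in n.children:
                walk(c)

        walk(self.root)
        return out

    def leaf_names(self) -> list[str]:
        return sorted(l.name for l in self.leaves())

    def bipartitions(self) -> set[frozenset[str]]:
        """Non-trivial bipartitions, each canonicalised as the side that
        excludes the lexicographically smallest leaf."""
        all_leaves = frozenset(self.leaf_names())
        ref = min(all_leaves)
        splits: set[frozenset[str]] = set()

        def walk(n: Node) -> frozenset[str]:
            if n.is_leaf():
                return frozenset([n.name])
            below = frozenset().union(*(walk(c) for c in n.children))
            if n is not self.root and 1 < len(below) < len(all_leaves) - 1:
                side = below if ref not in below else all_leaves - below
                splits.add(side)
            return below

        walk(self.root)
        return splits

    def newick(self) -> str:
        def fmt(n: Node) -> str:
            if n.is_leaf():
                return f"{n.name}:{n.length:.6f}"
            inner = ",".join(fmt(c) for c in n.children)
            label = n.name or ""
            return f"({inner}){label}:{n.length:.6f}"

        inner = ",".join(fmt(c) for c in self.root.children)
        return f"({inner});"

    @classmethod
    def from_newick(cls, text: str) -> "Tree":
        text = text.strip().rstrip(";")
        pos = 0

        def parse() -> Node:
            nonlocal pos
            node = Node()
            if text[pos] == "(":
                pos += 1
                while True:
                    node.children.append(parse())
                    if text[pos] == ",":
                        pos += 1
                    elif text[pos] == ")":
                        pos += 1
                        break
            # label
            start = pos
            while pos < len(text) and text[pos] not in ",():":
                pos += 1
            node.name = text[start:pos]
            if pos < len(text) and text[pos] == ":":
                pos += 1
                start = pos
                while pos < len(text) and text[pos] not in ",()":
                    pos += 1
                node.length = float(text[start:pos])
            return node

        return cls(parse())


def nj_tree(dm: DistanceMatrix) -> Tree:
    """Saitou–Nei neighbor joining with the canonical Q-criterion.

    Ties on Q are broken by the lowest (i, j) taxon-index pair, so the
    result is deterministic.  Negative branch lengths are clamped to 0.
    The returned tree is unrooted (root has three children).
    """
    n = len(dm.taxa)
    if n < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")
    d = dm.d.astype(float).copy()
    nodes = [Node(name) for name in dm.taxa]
    active = list(range(n))
    while len(active) > 3:
        m = len(active)
        sub = d[np.ix_(active, active)]
        r = sub.sum(axis=1)
        q = (m - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        # lowest index pair among minima
        qmin = q.min()
        ii, jj = np.argwhere(np.isclose(q, qmin, rtol=0, atol=1e-12))[0]
        if ii > jj:
            ii, jj = jj, ii
        i_g, j_g = active[ii], active[jj]
        dij = d[i_g, j_g]
        li = 0.5 * dij + (r[ii] - r[jj]) / (2 * (m - 2))
        lj = dij - li
        li, lj = max(li, 0.0), max(lj, 0.0)
        parent = Node()
        nodes[i_g].length = li
        nodes[j_g].length = lj
        parent.children = [nodes[i_g], nodes[j_g]]
        # distances from the new node
        new_row = 0.5 * (d[i_g, :] + d[j_g, :] - dij)
        d = np.vstack([d, new_row])
        new_col = np.append(new_row, 0.0)
        d = np.column_stack([d, new_col])
        nodes.append(parent)
        active = [g for g in active if g not in (i_g, j_g)] + [len(nodes) - 1]
    # final three-way join
    a, b, c = active
    root = Node()
    la = 0.5 * (d[a, b] + d[a, c] - d[b, c])
    lb = 0.5 * (d[a, b] + d[b, c] - d[a, c])
    lc = 0.5 * (d[a, c] + d[b, c] - d[a, b])
    for g, L in ((a, la), (b, lb), (c, lc)):
        nodes[g].length = max(L, 0.0)
        root.children.append(nodes[g])
    return Tree(root)


def rf_distance(t1: Tree, t2: Tree) -> int:
    """Robinson–Foulds distance: symmetric difference of non-trivial splits."""
    if t1.leaf_names() != t2.leaf_names():
        raise ValueError("trees have different leaf sets")
    b1, b2 = t1.bipartitions(), t2.bipartitions()
    return len(b1 ^ b2)


def clade_membership(tree: Tree, groups: dict[str, set[str]]) -> dict[str, bool]:
    """Monophyly of each labelled taxon group.

    A group is monophyletic iff one of the tree's bipartitions equals it.
    Groups of size < 2 (or covering all but one taxon) are vacuously
    monophyletic.
    """
    splits = tree.bipartitions()
    all_leaves = frozenset(tree.leaf_names())
    ref = min(all_leaves)
    out = {}
    for label, members in groups.items():
        members = frozenset(members)
        if len(members) < 2 or len(all_leaves - members) < 2:
            out[label] = True
            continue
        side = members if ref not in members else all_leaves - members
        out[label] = side in splits
    return out


@dataclass
class SegmentPartition:
    """Ordered (label, alignment-column interval) list; 0-based half-open."""

    segments: list[tuple[str, tuple[int, int]]]

    def __post_init__(self) -> None:
        prev_end = -1
        seen = set()
        for label, (s, e) in self.segments:
            if not (0 <= s < e):
                raise ValueError(f"segment {label}: invalid interval")
            if label in seen:
                raise ValueError(f"duplicate segment label {label}")
            seen.add(label)
        ordered = sorted(self.segments, key=lambda t: t[1][0])
        for (l1, (s1, e1)), (l2, (s2, e2)) in zip(ordered, ordered[1:]):
            if s2 < e1:
                raise ValueError(f"segments {l1} and {l2} overlap")

    @classmethod
    def read_tsv(cls, path) -> "SegmentPartition":
        """TSV: label, start, end with 1-based inclusive columns."""
        segs = []
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                label, s, e = line.split("\t")[:3]
                segs.append((label, (int(s) - 1, int(e))))
        return cls(segs)


@dataclass
class IncongruenceReport:
    segment_trees: dict[str, Tree]
    rf: dict[tuple[str, str], int]
    flagged: list[tuple[str, str, int]]  # adjacent segment pair + boundary column
    skipped: list[str] = field(default_factory=list)

    def rf_matrix(self) -> tuple[list[str], np.ndarray]:
        labels = list(self.segment_trees)
        m = np.zeros((len(labels), len(labels)), dtype=int)
        for (a, b), v in self.rf.items():
            i, j = labels.index(a), labels.index(b)
            m[i, j] = m[j, i] = v
        return labels, m


def congruence_scan(
    names: list[str],
    rows: list[str],
    partition: SegmentPartition,
    min_columns: int = 50,
    theta: float | None = None,
) -> IncongruenceReport:
    """Per-segment NJ trees on T92 distances and pairwise RF incongruence.

    Segments with fewer than ``min_columns`` valid columns, or containing a
    saturated pair, are skipped with a warning.  Adjacent analysed segments
    with RF > 0 are flagged as candidate gene-conversion breakpoints at
    their shared boundary.  With only three taxa there is a single unrooted
    topology, so no flags are possible.
    """
    if len(names) < 3:
        raise ValueError("need at least 3 taxa")
    trees: dict[str, Tree] = {}
    skipped: list[str] = []
    ordered = sorted(partition.segments, key=lambda t: t[1][0])
    for label, (s, e) in ordered:
        seg_rows = [r[s:e] for r in rows]
        min_valid = min(
            sum(1 for c in r if c not in "-N") for r in seg_rows
        )
        if min_valid < min_columns:
            print(f"warning: segment {label}: only {min_valid} valid columns, skipped", file=sys.stderr)
            skipped.append(label)
            continue
        try:
            dm = DistanceMatrix.from_alignment(names, seg_rows, theta=theta)
        except (SaturationError, ValueError) as exc:
            print(f"warning: segment {label}: {exc}; skipped", file=sys.stderr)
            skipped.append(label)
            continue
        trees[label] = nj_tree(dm)
    rf: dict[tuple[str, str], int] = {}
    labels = list(trees)
    for a, b in itertools.combinations(labels, 2):
        rf[(a, b)] = rf_distance(trees[a], trees[b])
    flagged: list[tuple[str, str, int]] = []
    if len(names) >= 4:
        analysed = [(label, iv) for label, iv in ordered if label in trees]
        for (l1, (s1, e1)), (l2, (s2, e2)) in zip(analysed, analysed[1:]):
            key = (l1, l2) if (l1, l2) in rf else (l2, l1)
            if rf[key] > 0:
                flagged.append((l1, l2, e1))
    return IncongruenceReport(segment_trees=trees, rf=rf, flagged=flagged, skipped=skipped)
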