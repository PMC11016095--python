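"""Distance-based phylogenetics for species-group delimitation.

Implements the classical pipeline used to delimit barcode clades: pairwise
distances under p-distance / JC69 / K2P, Saitou-Nei neighbour joining,
nonparametric bootstrap over alignment columns, outgroup rooting and Newick
export.  Bootstrap supports are reported as integer percentages on the
internal edges of the point-estimate tree.

The NJ implementation is deterministic: ties in the Q-criterion are broken
by the lexicographically smallest pair of cluster labels (a cluster is
labelled by its smallest leaf id), and negative branch lengths are clamped
to zero with the deficit transferred to the sister edge so that exported
Newick is valid for downstream tools.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .alignment import Alignment

__all__ = [
    "DistanceModel",
    "GapPolicy",
    "DistanceMatrix",
    "TreeNode",
    "pairwise_distance",
    "neighbour_joining",
    "bootstrap_support",
    "root_with_outgroup",
    "to_newick",
    "bipartitions",
]


class PhyloError(ValueError):
    pass


class SaturationError(PhyloError):
    """A corrected distance is undefined (log of a non-positive number)."""


class DistanceModel:
    P_DIST = "P_DIST"
    JC69 = "JC69"
    K2P = "K2P"


class GapPolicy:
    PAIRWISE_DELETE = "PAIRWISE_DELETE"
    COMPLETE_DELETE = "COMPLETE_DELETE"


@dataclass(frozen=True)
class DistanceMatrix:
    labels: tuple[str, ...]
    values: np.ndarray  # symmetric, zero diagonal; np.inf marks saturation
    saturated: frozenset[tuple[str, str]] = frozenset()

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != (len(self.labels), len(self.labels)):
            raise PhyloError("distance matrix shape does not match labels")
        if not np.allclose(v, v.T, equal_nan=True):
            raise PhyloError("distance matrix not symmetric")
        if np.any(np.diag(v) != 0):
            raise PhyloError("distance matrix diagonal must be zero")
        finite = v[np.isfinite(v)]
        if np.any(finite < 0):
            raise PhyloError("negative distances")
        object.__setattr__(self, "values", v)
        object.__setattr__(self, "labels", tuple(self.labels))

    def __getitem__(self, pair: tuple[str, str]) -> float:
        i, j = self.labels.index(pair[0]), self.labels.index(pair[1])
        return float(self.values[i, j])

    def to_tsv(self, path) -> None:
        """Write a square labelled distance matrix as TSV."""
        with open(path, "w") as fh:
            fh.write("id\t" + "\t".join(self.labels) + "\n")
            for lab, row in zip(self.labels, self.values):
                fh.write(lab + "\t" + "\t".join(f"{v:.6g}" for v in row) + "\n")


# integer encoding for vectorised distance computation: A,G purines 0/1,
# C,T pyrimidines 2/3, everything else (gap, N, ambiguity) = missing
_ENC = np.full(128, 255, dtype=np.uint8)
for _i, _b in enumerate("AGCT"):
    _ENC[ord(_b)] = _i


def _encode_row(row: str) -> np.ndarray:
    return _ENC[np.frombuffer(row.encode("ascii"), dtype=np.uint8)]


def _pair_distance(a: np.ndarray, b: np.ndarray, model: str) -> tuple[float, bool]:
    """Distance for one encoded row pair; returns (d, saturated)."""
    ok = (a != 255) & (b != 255)
    n_comp = int(ok.sum())
    if n_comp == 0:
        raise PhyloError("no comparable sites for a sequence pair")
    diff = ok & (a != b)
    n_diff = int(diff.sum())
    # transitions stay within the purine (0,1) or pyrimidine (2,3) pair
    n_ts = int((diff & ((a < 2) == (b < 2))).sum())
    n_tv = n_diff - n_ts
    p = n_diff / n_comp
    if model == DistanceModel.P_DIST:
        return p, False
    if model == DistanceModel.JC69:
        arg = 1.0 - 4.0 * p / 3.0
        if arg <= 0:
            return math.inf, True
        return -0.75 * math.log(arg), False
    if model == DistanceModel.K2P:
        P, Q = n_ts / n_comp, n_tv / n_comp
        a1, a2 = 1.0 - 2.0 * P - Q, 1.0 - 2.0 * Q
        if a1 <= 0 or a2 <= 0:
            return math.inf, True
        return -0.5 * math.log(a1) - 0.25 * math.log(a2), False
    raise PhyloError(f"unknown distance model {model!r}")


def pairwise_distance(
    aln: Alignment,
    model: str = DistanceModel.K2P,
    gap_policy: str = GapPolicy.PAIRWISE_DELETE,
    on_saturation: str = "flag",
) -> DistanceMatrix:
    """Pairwise distance matrix under the chosen substitution model.

    Sites with a gap or ambiguity code in either row of a pair are excluded
    (PAIRWISE_DELETE); COMPLETE_DELETE first removes every column containing
    any gap/ambiguity in any row.  Saturated corrected distances become
    ``inf`` and are recorded (``on_saturation='raise'`` errors instead).
    """
    rows = [_encode_row(r.residues) for r in aln.records]
    labels = tuple(r.id for r in aln.records)
    if gap_policy == GapPolicy.COMPLETE_DELETE:
        keep = np.ones(aln.ncol, dtype=bool)
        for row in rows:
            keep &= row != 255
        rows = [row[keep] for row in rows]
    elif gap_policy != GapPolicy.PAIRWISE_DELETE:
        raise PhyloError(f"unknown gap policy {gap_policy!r}")
    return _dm_from_encoded(rows, labels, model, on_saturation)


def _dm_from_encoded(
    rows: list[np.ndarray], labels: tuple[str, ...], model: str, on_saturation: str
) -> DistanceMatrix:
    n = len(rows)
    d = np.zeros((n, n))
    saturated: set[tuple[str, str]] = set()
    for i in range(n):
        for j in range(i + 1, n):
            dij, sat = _pair_distance(rows[i], rows[j], model)
            if sat:
                if on_saturation == "raise":
                    raise SaturationError(
                        f"saturated {model} distance between {labels[i]!r} and {labels[j]!r}"
                    )
                saturated.add((labels[i], labels[j]))
            d[i, j] = d[j, i] = dij
    return DistanceMatrix(labels, d, frozenset(saturated))


# ---------------------------------------------------------------------------
# trees
# ---------------------------------------------------------------------------

@dataclass
class TreeNode:
    """Rooted representation of a (possibly unrooted) tree.

    Unrooted trees are stored with a trifurcating root.  ``length`` is the
    edge to the parent (None at the root); ``support`` is an integer
    bootstrap percentage on internal edges.
    """

    name: str | None = None
    length: float | None = None
    support: int | None = None
    children: list["TreeNode"] = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list["TreeNode"]:
        if self.is_leaf:
            return [self]
        out: list[TreeNode] = []
        for c in self.children:
            out.extend(c.leaves())
        return out

    def leaf_names(self) -> frozenset[str]:
        return frozenset(l.name for l in self.leaves())

    def preorder(self) -> Iterable["TreeNode"]:
        yield self
        for c in self.children:
            yield from c.preorder()


def bipartitions(tree: TreeNode) -> dict[frozenset[str], TreeNode]:
    """Non-trivial splits of an (un)rooted tree, canonically oriented.

    Each split is represented by the side NOT containing the overall
    lexicographically smallest leaf, so the representation is invariant to
    rooting and leaf order.  Maps split -> the child node below the edge.
    """
    all_leaves = tree.leaf_names()
    ref = min(all_leaves)
    out: dict[frozenset[str], TreeNode] = {}
    for node in tree.preorder():
        if node is tree or node.is_leaf:
            continue
        below = node.leaf_names()
        side = all_leaves - below if ref in below else below
        if 2 <= len(side) <= len(all_leaves) - 2:
            out[side] = node
    return out


def to_newick(tree: TreeNode, include_support: bool = True) -> str:
    def fmt(node: TreeNode) -> str:
        if node.is_leaf:
            label = node.name or ""
        else:
            inner = ",".join(fmt(c) for c in node.children)
            label = f"({inner})"
            if include_support and node.support is not None:
                label += str(node.support)
        if node.length is not None:
            label += f":{node.length:.6g}"
        return label

    return fmt(tree) + ";"


# ---------------------------------------------------------------------------
# neighbour joining
# ---------------------------------------------------------------------------

def neighbour_joining(dm: DistanceMatrix) -> TreeNode:
    """Saitou-Nei neighbour joining; returns an unrooted tree
    (trifurcating root) with nonnegative branch lengths."""
    n = len(dm.labels)
    if n < 3:
        raise PhyloError("neighbour joining needs at least 3 labels")
    if not np.all(np.isfinite(dm.values)):
        raise PhyloError("distance matrix contains saturated (infinite) entries")
    # active clusters: key = smallest leaf label (deterministic tie-break)
    nodes: dict[str, TreeNode] = {
        lab: TreeNode(name=lab) for lab in dm.labels
    }
    D: dict[tuple[str, str], float] = {}
    labs = sorted(dm.labels)
    for i, a in enumerate(dm.labels):
        for j, b in enumerate(dm.labels):
            if a != b:
                D[(a, b)] = float(dm.values[i, j])
    active = set(dm.labels)

    def d(a: str, b: str) -> float:
        return D[(a, b)]

    while len(active) > 3:
        m = len(active)
        keys = sorted(active)
        r = {a: sum(d(a, b) for b in active if b != a) for a in active}
        best_pair: tuple[str, str] | None = None
        best_q = math.inf
        for ia in range(len(keys)):
            for ib in range(ia + 1, len(keys)):
                a, b = keys[ia], keys[ib]
                q = (m - 2) * d(a, b) - r[a] - r[b]
                if q < best_q - 1e-12 or (
                    abs(q - best_q) <= 1e-12 and (best_pair is None or (a, b) < best_pair)
                ):
                    best_q, best_pair = q, (a, b)
        a, b = best_pair  # type: ignore[misc]
        la = 0.5 * d(a, b) + (r[a] - r[b]) / (2 * (m - 2))
        lb = d(a, b) - la
        # clamp negatives, moving the deficit to the sister edge
        if la < 0:
            lb += la
            la = 0.0
        if lb < 0:
            la += lb
            lb = 0.0
        la, lb = max(la, 0.0), max(lb, 0.0)
        parent = TreeNode(
            children=[
                TreeNode(name=nodes[a].name, length=la, support=nodes[a].support,
                         children=nodes[a].children),
                TreeNode(name=nodes[b].name, length=lb, support=nodes[b].support,
                         children=nodes[b].children),
            ]
        )
        new_key = min(a, b)
        dab = d(a, b)
        for c in active - {a, b}:
            dnew = 0.5 * (d(a, c) + d(b, c) - dab)
            D[(new_key, c)] = D[(c, new_key)] = max(dnew, 0.0)
        active -= {a, b}
        nodes.pop(a), nodes.pop(b)
        nodes[new_key] = parent
        active.add(new_key)
    # join the final three clusters at a trifurcating root
    x, y, z = sorted(active)
    dxy, dxz, dyz = d(x, y), d(x, z), d(y, z)
    lx = 0.5 * (dxy + dxz - dyz)
    ly = 0.5 * (dxy + dyz - dxz)
    lz = 0.5 * (dxz + dyz - dxy)
    root_children = []
    for key, length in ((x, lx), (y, ly), (z, lz)):
        nd = nodes[key]
        root_children.append(
            TreeNode(name=nd.name, length=max(length, 0.0), support=nd.support,
                     children=nd.children)
        )
    return TreeNode(children=root_children)


# ---------------------------------------------------------------------------
# bootstrap
# ---------------------------------------------------------------------------

def bootstrap_support(
    aln: Alignment,
    model: str = DistanceModel.K2P,
    n_replicates: int = 1000,
    seed: int = 0,
    gap_policy: str = GapPolicy.PAIRWISE_DELETE,
) -> TreeNode:
    """Point-estimate NJ tree with bootstrap supports on internal edges.

    Alignment columns are resampled with replacement per replicate; the
    support of an internal edge is the percentage of replicate trees that
    contain the same bipartition.  Deterministic for a fixed seed.
    """
    if n_replicates < 1:
        raise PhyloError("n_replicates must be >= 1")
    if aln.ncol == 1:
        warnings.warn("bootstrapping a 1-column alignment is degenerate")
    point = neighbour_joining(pairwise_distance(aln, model, gap_policy))
    splits = bipartitions(point)
    counts = {s: 0 for s in splits}
    rng = np.random.default_rng(seed)
    # rows visited in id order so supports are invariant to input leaf order
    order = sorted(range(aln.nrow), key=lambda i: aln.records[i].id)
    labels = tuple(aln.records[i].id for i in order)
    enc = [_encode_row(aln.records[i].residues) for i in order]
    if gap_policy == GapPolicy.COMPLETE_DELETE:
        keep = np.ones(aln.ncol, dtype=bool)
        for row in enc:
            keep &= row != 255
        enc = [row[keep] for row in enc]
    ncol = enc[0].size
    for _ in range(n_replicates):
        cols = rng.integers(0, ncol, size=ncol)
        rep_rows = [row[cols] for row in enc]
        rep_dm = _dm_from_encoded(rep_rows, labels, model, "flag")
        rep_tree = neighbour_joining(rep_dm)
        rep_splits = bipartitions(rep_tree)
        for s in counts:
            if s in rep_splits:
                counts[s] += 1
    for s, node in splits.items():
        node.support = round(100 * counts[s] / n_replicates)
    return point


# ---------------------------------------------------------------------------
# rooting
# ---------------------------------------------------------------------------

def _adjacency(tree: TreeNode) -> tuple[list[TreeNode], dict[int, list[tuple[int, float, int | None]]]]:
    """Undirected adjacency over node objects; edges carry (length, support)."""
    nodes: list[TreeNode] = list(tree.preorder())
    index = {id(n): i for i, n in enumerate(nodes)}
    adj: dict[int, list[tuple[int, float, int | None]]] = {i: [] for i in range(len(nodes))}
    for node in nodes:
        for child in node.children:
            i, j = index[id(node)], index[id(child)]
            length = child.length if child.length is not None else 0.0
            adj[i].append((j, length, child.support))
            adj[j].append((i, length, child.support))
    return nodes, adj


def root_with_outgroup(tree: TreeNode, outgroup_ids: Sequence[str]) -> TreeNode:
    """Root an unrooted tree on the edge separating the outgroup clade.

    The outgroup ids must form a clade (one side of some edge, or a single
    leaf); the root splits that edge into two equal halves.
    """
    og = frozenset(outgroup_ids)
    all_leaves = tree.leaf_names()
    if not og or not og <= all_leaves:
        raise PhyloError("outgroup ids must be a non-empty subset of the leaf set")
    nodes, adj = _adjacency(tree)

    def leafset_away(i: int, j: int) -> frozenset[str]:
        """Leaves on node j's side of edge (i, j)."""
        out: set[str] = set()
        stack = [(i, j)]
        while stack:
            prev, cur = stack.pop()
            if not adj[cur] or all(nb == prev for nb, _, _ in adj[cur]):
                pass
            if nodes[cur].is_leaf:
                out.add(nodes[cur].name)
            for nb, _, _ in adj[cur]:
                if nb != prev:
                    stack.append((cur, nb))
        return frozenset(out)

    edge = None
    for i in adj:
        for j, length, support in adj[i]:
            if i < j:
                below = leafset_away(i, j)
                if below == og:
                    edge = (i, j, length, support)
                elif all_leaves - below == og:
                    edge = (j, i, length, support)
    if edge is None:
        raise PhyloError("outgroup is not monophyletic in the unrooted tree")
    og_side, in_side, length, support = edge

    def build(cur: int, prev: int) -> TreeNode:
        node = nodes[cur]
        kids = []
        for nb, ln, sup in adj[cur]:
            if nb == prev:
                continue
            child = build(nb, cur)
            child.length = ln
            child.support = sup
            kids.append(child)
        return TreeNode(name=node.name if node.is_leaf else None, children=kids)

    og_sub = build(og_side, in_side)
    in_sub = build(in_side, og_side)
    og_sub.length = length / 2.0
    in_sub.length = length / 2.0
    og_sub.support = support
    in_sub.support = support
    return TreeNode(children=[og_sub, in_sub])
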