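import numpy as np
import pytest

import barcodiag as bd
from barcodiag import PrimerRole, PrimerSpec, Strand
from barcodiag.phylo import DistanceMatrix
from barcodiag.seqio import Group, SequenceRecord


def random_additive_tree(rng, n_leaves):
    """Random unrooted binary tree with positive branch lengths.

    Returns (DistanceMatrix of path lengths, set of non-trivial splits in
    canonical form, labels).
    """
    labels = [f"L{i}" for i in range(n_leaves)]
    edges = {}
    nxt = n_leaves
    center = nxt
    nxt += 1
    for i in range(3):
        edges[(center, i)] = rng.uniform(0.05, 1.0)
    for leaf in range(3, n_leaves):
        u, v = list(edges)[rng.integers(0, len(edges))]
        length = edges.pop((u, v))
        mid = nxt
        nxt += 1
        split = rng.uniform(0.25, 0.75)
        edges[(u, mid)] = length * split
        edges[(mid, v)] = length * (1 - split)
        edges[(mid, leaf)] = rng.uniform(0.05, 1.0)
    adj = {}
    for (u, v), ln in edges.items():
        adj.setdefault(u, []).append((v, ln))
        adj.setdefault(v, []).append((u, ln))

    def dists_from(src):
        out = {src: 0.0}
        stack = [src]
        while stack:
            cur = stack.pop()
            for nb, ln in adj[cur]:
                if nb not in out:
                    out[nb] = out[cur] + ln
                    stack.append(nb)
        return out

    d = np.zeros((n_leaves, n_leaves))
    for i in range(n_leaves):
        di = dists_from(i)
        for j in range(n_leaves):
            d[i, j] = di[j]
    splits = set()
    for (u, v) in edges:
        side = set()
        stack = [(u, v)]
        while stack:
            prev, cur = stack.pop()
            if cur < n_leaves:
                side.add(f"L{cur}")
            for nb, _ in adj[cur]:
                if nb != prev:
                    stack.append((cur, nb))
        if 2 <= len(side) <= n_leaves - 2:
            canon = frozenset(side) if "L0" not in side else frozenset(
                set(labels) - side
            )
            splits.add(canon)
    return DistanceMatrix(tuple(labels), d), splits, labels


def tree_path_distances(tree, labels):
    """Leaf-to-leaf path-length matrix of a TreeNode tree."""
    adj = {}

    def walk(node):
        for c in node.children:
            adj.setdefault(id(node), []).append((id(c), c.length))
            adj.setdefault(id(c), []).append((id(node), c.length))
            walk(c)

    walk(tree)
    leaf_ids = {l.name: id(l) for l in tree.leaves()}
    n = len(labels)
    out = np.zeros((n, n))
    for i, a in enumerate(labels):
        dist = {leaf_ids[a]: 0.0}
        stack = [leaf_ids[a]]
        while stack:
            cur = stack.pop()
            for nb, ln in adj.get(cur, []):
                if nb not in dist:
                    dist[nb] = dist[cur] + ln
                    stack.append(nb)
        for j, b in enumerate(labels):
            out[i, j] = dist[leaf_ids[b]]
    return out


def make_alignment(rows, groups=None, species=None):
    """Build an Alignment from {id: residues} with optional role/species maps."""
    groups = groups or {}
    species = species or {}
    recs = [
        SequenceRecord(
            rid,
            res,
            species=species.get(rid, rid.rstrip("0123456789_")),
            group=groups.get(rid, Group.UNKNOWN),
        )
        for rid, res in rows.items()
    ]
    return bd.Alignment(tuple(recs))


@pytest.fixture(scope="session")
def genus():
    """Default coding-marker synthetic genus (seed 11) with its truth ledger."""
    cfg = bd.default_genus_config(seed=11)
    records, truth = bd.simulate_genus(cfg)
    return cfg, records, truth


@pytest.fixture(scope="session")
def genus_assays(genus):
    """Complementary duplex assay pair designed on the default genus."""
    cfg, records, truth = genus
    aln = truth.alignment
    sites = bd.scan_diagnostic_snps(aln)
    feasible = [s for s in sites if bd.arms_context_screen(aln, s)[0]]
    fwd = PrimerSpec("uni_fw", cfg.fwd_flank, PrimerRole.UNIVERSAL_FWD, Strand.PLUS)
    rev = PrimerSpec("uni_rv", cfg.rev_primer, PrimerRole.UNIVERSAL_REV, Strand.MINUS)
    assay_a, assay_b = bd.design_complementary_assays(
        aln, feasible[0], fwd, rev, site_nontarget=feasible[1]
    )
    return assay_a, assay_b
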