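"""Tree construction and monophyly assessment.

Neighbor joining (Saitou-Nei, exact on additive matrices) with nonparametric
bootstrap supports, Fitch small-parsimony scoring with greedy
nearest-neighbor-interchange search, and rank-level monophyly percentages.
Monophyly is assessed on the unrooted tree: a taxon is monophyletic when some
edge bipartitions the leaves into exactly that taxon versus the rest, so no
outgroup or rooting scheme is required. Trees are dendropy objects; bootstrap
supports are carried as internal-node labels (percent).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import dendropy
import numpy as np

from .data_model import LocusAlignment, TaxonLabel
from .distances import DistanceMatrix, DistanceModelParams, encode_sequence

logger = logging.getLogger(__name__)

PhyloTree = dendropy.Tree


# ---------------------------------------------------------------------------
# Neighbor joining
# ---------------------------------------------------------------------------

def neighbor_joining(m: DistanceMatrix) -> PhyloTree:
    """Saitou-Nei neighbor joining on a fully defined distance matrix.

    Deterministic: Q-criterion ties are broken by the first (row-major) pair.
    Negative branch-length estimates are clamped to zero with the total
    deficit logged. Exact (topology and path lengths) on additive inputs.
    """
    if m.n < 3:
        raise ValueError("neighbor joining needs at least 3 specimens")
    if np.isnan(m.d).any():
        raise ValueError(
            "distance matrix has undefined entries; exclude or impute them first"
        )
    tns = dendropy.TaxonNamespace(m.ids)
    nodes: list[dendropy.Node] = []
    for sid in m.ids:
        node = dendropy.Node(taxon=tns.get_taxon(sid))
        nodes.append(node)
    D = m.d.astype(float).copy()
    clamp_deficit = 0.0

    def set_len(node: dendropy.Node, length: float) -> None:
        nonlocal clamp_deficit
        if length < 0:
            clamp_deficit += -length
            length = 0.0
        node.edge.length = float(length)

    while len(nodes) > 3:
        r = len(nodes)
        R = D.sum(axis=1)
        Q = (r - 2) * D - R[:, None] - R[None, :]
        np.fill_diagonal(Q, np.inf)
        i, j = np.unravel_index(int(np.argmin(Q)), Q.shape)
        if i > j:
            i, j = j, i
        li = 0.5 * D[i, j] + (R[i] - R[j]) / (2.0 * (r - 2))
        lj = D[i, j] - li
        u = dendropy.Node()
        set_len(nodes[i], li)
        set_len(nodes[j], lj)
        u.add_child(nodes[i])
        u.add_child(nodes[j])
        d_new = 0.5 * (D[i] + D[j] - D[i, j])
        keep = [k for k in range(r) if k not in (i, j)]
        D2 = np.empty((r - 1, r - 1))
        D2[: r - 2, : r - 2] = D[np.ix_(keep, keep)]
        D2[-1, : r - 2] = d_new[keep]
        D2[: r - 2, -1] = d_new[keep]
        D2[-1, -1] = 0.0
        D = D2
        nodes = [nodes[k] for k in keep] + [u]

    root = dendropy.Node()
    d01, d02, d12 = D[0, 1], D[0, 2], D[1, 2]
    lengths = [(d01 + d02 - d12) / 2.0, (d01 + d12 - d02) / 2.0, (d02 + d12 - d01) / 2.0]
    for node, length in zip(nodes, lengths):
        set_len(node, length)
        root.add_child(node)
    if clamp_deficit > 0:
        logger.info("neighbor joining clamped negative branch lengths (total %.3g)", clamp_deficit)
    tree = dendropy.Tree(taxon_namespace=tns)
    tree.seed_node = root
    tree.is_rooted = False
    return tree


# ---------------------------------------------------------------------------
# Bipartitions and monophyly
# ---------------------------------------------------------------------------

def leaf_labels(tree: PhyloTree) -> list[str]:
    return [lf.taxon.label for lf in tree.leaf_node_iter()]


def _support_of(node: dendropy.Node) -> float | None:
    if node.label is None:
        return None
    try:
        return float(node.label)
    except ValueError:
        return None


def edge_bipartitions(tree: PhyloTree) -> dict[frozenset, float | None]:
    """Map each edge's child-side leaf set to that edge's support (or None).

    Includes trivial (single-leaf) sides; excludes the full leaf set.
    """
    all_leaves = frozenset(leaf_labels(tree))
    below: dict[int, frozenset] = {}
    out: dict[frozenset, float | None] = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            below[id(node)] = frozenset([node.taxon.label])
        else:
            s = frozenset().union(*(below[id(c)] for c in node.child_nodes()))
            below[id(node)] = s
        if node.parent_node is not None:
            side = below[id(node)]
            if side != all_leaves:
                sup = None if node.is_leaf() else _support_of(node)
                # keep the best support if the same split appears twice
                if side not in out or (sup is not None and (out[side] is None or sup > out[side])):
                    out[side] = sup
    return out


def split_set(tree: PhyloTree) -> set[frozenset]:
    """Non-trivial splits, normalized to the side not containing a reference leaf."""
    all_leaves = frozenset(leaf_labels(tree))
    ref = min(all_leaves)
    splits = set()
    for side in edge_bipartitions(tree):
        if len(side) < 2 or len(side) > len(all_leaves) - 2:
            continue
        splits.add(side if ref not in side else all_leaves - side)
    return splits


@dataclass(frozen=True)
class MonophylyConfig:
    rank: str = "species"
    support_min: float = 70.0
    require_support: bool = True

    def __post_init__(self) -> None:
        if not 0 <= self.support_min <= 100:
            raise ValueError("support_min must be in [0, 100]")


@dataclass
class MonophylyReport:
    rank: str
    per_taxon: dict[str, str]  # verdict per taxon
    percent: float
    n_assessable: int
    singletons: list[str] = field(default_factory=list)


def taxon_leaf_sets(
    tree: PhyloTree, labels: Mapping[str, TaxonLabel | str], rank: str
) -> dict[str, frozenset]:
    groups: dict[str, set] = {}
    for leaf in leaf_labels(tree):
        lab = labels.get(leaf)
        name = lab.at_rank(rank) if isinstance(lab, TaxonLabel) else lab
        if not name:
            raise ValueError(f"leaf {leaf!r} has no label at rank {rank!r}")
        groups.setdefault(name, set()).add(leaf)
    return {k: frozenset(v) for k, v in groups.items()}


def _is_clade(
    S: frozenset, all_leaves: frozenset, biparts: Mapping[frozenset, float | None]
) -> tuple[bool, float | None]:
    """Whether leaf set S is a bipartition side of the unrooted tree."""
    if S == all_leaves:
        return True, None
    if S in biparts:
        return True, biparts[S]
    comp = all_leaves - S
    if comp in biparts:
        return True, biparts[comp]
    return False, None


def monophyly_percent(
    tree: PhyloTree,
    labels: Mapping[str, TaxonLabel | str],
    cfg: MonophylyConfig = MonophylyConfig(),
) -> MonophylyReport:
    """Rank-level monophyly verdicts and percentage over assessable taxa.

    Taxa with a single leaf are excluded. A monophyletic taxon counts towards
    the percentage only when its defining edge's support strictly exceeds
    ``support_min`` (when ``require_support``; edges without a support value
    count as unsupported).
    """
    all_leaves = frozenset(leaf_labels(tree))
    biparts = edge_bipartitions(tree)
    groups = taxon_leaf_sets(tree, labels, cfg.rank)
    per_taxon: dict[str, str] = {}
    singletons: list[str] = []
    for name, S in sorted(groups.items()):
        if len(S) < 2:
            per_taxon[name] = "excluded_singleton"
            singletons.append(name)
            continue
        mono, support = _is_clade(S, all_leaves, biparts)
        if not mono:
            per_taxon[name] = "non_monophyletic"
        elif support is not None and support > cfg.support_min:
            per_taxon[name] = "monophyletic_supported"
        else:
            per_taxon[name] = "monophyletic_unsupported"
    assessable = [v for v in per_taxon.values() if v != "excluded_singleton"]
    if cfg.require_support:
        good = sum(1 for v in assessable if v == "monophyletic_supported")
    else:
        good = sum(1 for v in assessable if v.startswith("monophyletic"))
    percent = 100.0 * good / len(assessable) if assessable else 0.0
    return MonophylyReport(
        rank=cfg.rank,
        per_taxon=per_taxon,
        percent=percent,
        n_assessable=len(assessable),
        singletons=singletons,
    )


def reference_clade_congruence(
    tree: PhyloTree,
    labels: Mapping[str, TaxonLabel | str],
    reference_groups: Mapping[str, Sequence[str]],
) -> dict[str, str]:
    """Score named groups of orders (an APG-style reference) against the tree.

    A group is recovered when the union of its orders' leaves forms a
    bipartition side of the unrooted tree. Groups naming an order absent from
    the tree are logged and skipped.
    """
    all_leaves = frozenset(leaf_labels(tree))
    biparts = edge_bipartitions(tree)
    order_leaves = taxon_leaf_sets(tree, labels, "order")
    out: dict[str, str] = {}
    for name, orders in reference_groups.items():
        missing = [o for o in orders if o not in order_leaves]
        if missing:
            logger.warning("group %r skipped: orders absent from tree: %s", name, missing)
            continue
        S = frozenset().union(*(order_leaves[o] for o in orders))
        mono, _ = _is_clade(S, all_leaves, biparts)
        out[name] = "recovered" if mono else "not_recovered"
    return out


# ---------------------------------------------------------------------------
# Bootstrap
# ---------------------------------------------------------------------------

from .distances import distance_matrix_from_codes as _distance_matrix_from_codes


def bootstrap_support(
    aln: LocusAlignment,
    params: DistanceModelParams,
    n_replicates: int = 1000,
    seed: int = 0,
) -> PhyloTree:
    """NJ tree with bootstrap supports (percent) on internal edges.

    Columns are resampled with replacement; each replicate's NJ splits are
    compared with the original tree's. Reproducible from ``seed``.
    """
    if aln.length < 1:
        raise ValueError("alignment has no columns")
    codes = np.vstack([encode_sequence(seq) for _, seq in aln.members])
    ids = aln.ids
    tree = neighbor_joining(_distance_matrix_from_codes(codes, ids, params))
    all_leaves = frozenset(ids)
    ref = min(all_leaves)
    counts: dict[frozenset, int] = {}
    rng = np.random.default_rng(seed)
    for _ in range(n_replicates):
        cols = rng.integers(0, aln.length, size=aln.length)
        rep_tree = neighbor_joining(
            _distance_matrix_from_codes(codes[:, cols], ids, params)
        )
        for split in split_set(rep_tree):
            counts[split] = counts.get(split, 0) + 1
    below: dict[int, frozenset] = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            below[id(node)] = frozenset([node.taxon.label])
            continue
        side = frozenset().union(*(below[id(c)] for c in node.child_nodes()))
        below[id(node)] = side
        if node.parent_node is None or len(side) < 2 or len(side) > len(all_leaves) - 2:
            continue
        key = side if ref not in side else all_leaves - side
        support = 100.0 * counts.get(key, 0) / n_replicates
        node.label = f"{support:g}"
    return tree


# ---------------------------------------------------------------------------
# Fitch parsimony and NNI search
# ---------------------------------------------------------------------------

# bitmasks A=1, C=2, G=4, T=8; gap/missing = any state
_FITCH_MASK = np.zeros(256, dtype=np.uint8)
for _ch, _m in (("A", 1), ("C", 2), ("G", 4), ("T", 8), ("N", 15), ("-", 15), ("?", 15)):
    _FITCH_MASK[ord(_ch)] = _m
    _FITCH_MASK[ord(_ch.lower())] = _m


def _seq_masks(aln: LocusAlignment) -> dict[str, np.ndarray]:
    masks = {}
    for sid, seq in aln.members:
        arr = _FITCH_MASK[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]
        if (arr == 0).any():
            pos = int(np.argmax(arr == 0))
            raise ValueError(f"{sid!r}: character {seq[pos]!r} not scorable at column {pos + 1}")
        masks[sid] = arr
    return masks


class _Unrooted:
    """Light mutable unrooted tree: adjacency over integer nodes."""

    def __init__(self, adj: dict[int, set[int]], leaf_label: dict[int, str]):
        self.adj = adj
        self.leaf_label = leaf_label

    def copy(self) -> "_Unrooted":
        return _Unrooted({k: set(v) for k, v in self.adj.items()}, dict(self.leaf_label))

    @classmethod
    def from_dendropy(cls, tree: PhyloTree) -> "_Unrooted":
        adj: dict[int, set[int]] = {}
        leaf_label: dict[int, str] = {}
        index: dict[int, int] = {}

        def nid(node) -> int:
            key = id(node)
            if key not in index:
                index[key] = len(index)
                adj[index[key]] = set()
            return index[key]

        for node in tree.preorder_node_iter():
            u = nid(node)
            if node.is_leaf():
                leaf_label[u] = node.taxon.label
            if node.parent_node is not None:
                v = nid(node.parent_node)
                adj[u].add(v)
                adj[v].add(u)
        # splice out degree-2 nodes (rooted representations)
        for u in [n for n in adj if len(adj[n]) == 2 and n not in leaf_label]:
            a, b = sorted(adj[u])
            adj[a].discard(u)
            adj[b].discard(u)
            adj[a].add(b)
            adj[b].add(a)
            del adj[u]
        return cls(adj, leaf_label)

    def postorder_edges(self) -> tuple[int, list[tuple[int, int]]]:
        """Root at an internal node; return (root, child->parent postorder)."""
        leaves = set(self.leaf_label)
        root = min(n for n in self.adj if n not in leaves) if len(self.adj) > 2 else min(self.adj)
        order: list[tuple[int, int]] = []
        stack = [(root, -1)]
        visit: list[tuple[int, int]] = []
        while stack:
            node, parent = stack.pop()
            visit.append((node, parent))
            for nb in sorted(self.adj[node]):
                if nb != parent:
                    stack.append((nb, node))
        for node, parent in reversed(visit):
            if parent != -1:
                order.append((node, parent))
        return root, order

    def internal_edges(self) -> list[tuple[int, int]]:
        leaves = set(self.leaf_label)
        out = []
        for u in sorted(self.adj):
            for v in sorted(self.adj[u]):
                if u < v and u not in leaves and v not in leaves:
                    out.append((u, v))
        return out

    def nni_neighbors(self, edge: tuple[int, int]) -> list["_Unrooted"]:
        """The two NNI rearrangements across an internal edge."""
        u, v = edge
        a, b = sorted(self.adj[u] - {v})
        x, y = sorted(self.adj[v] - {u})
        out = []
        for swap in (x, y):
            t = self.copy()
            t.adj[u].discard(b)
            t.adj[b].discard(u)
            t.adj[v].discard(swap)
            t.adj[swap].discard(v)
            t.adj[u].add(swap)
            t.adj[swap].add(u)
            t.adj[v].add(b)
            t.adj[b].add(v)
            out.append(t)
        return out

    def fitch_length(self, masks: Mapping[str, np.ndarray]) -> int:
        root, order = self.postorder_edges()
        L = len(next(iter(masks.values())))
        state: dict[int, np.ndarray] = {}
        changes = 0
        processed: dict[int, list[int]] = {n: [] for n in self.adj}
        for child, parent in order:
            processed[parent].append(child)
        # iterate nodes in postorder (children before parents)
        node_order = [c for c, _ in order] + [root]
        for node in node_order:
            if node in self.leaf_label:
                state[node] = masks[self.leaf_label[node]]
                continue
            kids = processed[node]
            s = state[kids[0]]
            for k in kids[1:]:
                inter = s & state[k]
                empty = inter == 0
                changes += int(empty.sum())
                s = np.where(empty, s | state[k], inter)
            state[node] = s
        return changes

    def to_newick(self) -> str:
        leaves = set(self.leaf_label)
        root = min(n for n in self.adj if n not in leaves) if len(self.adj) > 2 else min(self.adj)

        def emit(node: int, parent: int) -> str:
            if node in self.leaf_label:
                return self.leaf_label[node]
            parts = [emit(nb, node) for nb in sorted(self.adj[node]) if nb != parent]
            return "(" + ",".join(parts) + ")"

        return emit(root, -1) + ";"

    def to_dendropy(self, taxon_namespace=None) -> PhyloTree:
        tree = dendropy.Tree.get(
            data=self.to_newick(),
            schema="newick",
            preserve_underscores=True,
            taxon_namespace=taxon_namespace,
        )
        tree.is_rooted = False
        return tree


def fitch_length(tree: PhyloTree, aln: LocusAlignment) -> int:
    """Fitch small-parsimony length of a tree over an alignment.

    Gap and missing characters ('-', 'N', '?') are fully ambiguous (any
    nucleotide). Exact for binary (unrooted-binary) trees; for multifurcating
    nodes the sequential-intersection generalization is used.
    """
    masks = _seq_masks(aln)
    unrooted = _Unrooted.from_dendropy(tree)
    for node, label in unrooted.leaf_label.items():
        if label not in masks:
            raise ValueError(f"leaf {label!r} has no sequence in the alignment")
    return unrooted.fitch_length(masks)


def parsimony_search(
    aln: LocusAlignment,
    start: PhyloTree,
    max_rounds: int = 100,
) -> tuple[PhyloTree, int]:
    """Greedy NNI hill-climbing on Fitch length from a start tree.

    Steepest-descent with deterministic tie-breaking; stops at a local
    optimum or after ``max_rounds``. Returns (tree, parsimony length); the
    returned length never exceeds the start tree's.
    """
    masks = _seq_masks(aln)
    current = _Unrooted.from_dendropy(start)
    best_len = current.fitch_length(masks)
    for _ in range(max_rounds):
        best_move = None
        move_len = best_len
        for edge in current.internal_edges():
            for t in current.nni_neighbors(edge):
                L = t.fitch_length(masks)
                if L < move_len:
                    move_len, best_move = L, t
        if best_move is None:
            break
        current, best_len = best_move, move_len
    return current.to_dendropy(taxon_namespace=start.taxon_namespace), best_len


def read_newick(path_or_str: str, from_path: bool = True) -> PhyloTree:
    """Read a newick tree, preserving underscores in labels."""
    kwargs = {"path": path_or_str} if from_path else {"data": path_or_str}
    return dendropy.Tree.get(schema="newick", preserve_underscores=True, **kwargs)


def write_newick(tree: PhyloTree) -> str:
    return tree.as_string(
        schema="newick", unquoted_underscores=True, suppress_rooting=True
    ).strip() + "\n"
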