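import numpy as np
import pytest

from barcode_eval.data_model import LocusAlignment, MultiLocusDataset, SpecimenRecord, TaxonLabel
from barcode_eval.synthetic_data import SimulationConfig, simulate_dataset


def make_label(sp: str, genus: str | None = None, family: str | None = None,
               order: str = "") -> TaxonLabel:
    return TaxonLabel(
        species=sp,
        genus=genus or f"G_{sp}",
        family=family or f"F_{sp}",
        order=order,
    )


def toy_dataset(seqs_by_locus: dict[str, dict[str, str]],
                species_of: dict[str, str]) -> MultiLocusDataset:
    """Assemble a dataset from {locus: {specimen: seq}} plus species labels."""
    ids: list[str] = []
    for d in seqs_by_locus.values():
        for sid in d:
            if sid not in ids:
                ids.append(sid)
    specimens = [
        SpecimenRecord(
            specimen_id=sid,
            morph=make_label(species_of[sid]),
            sequence_by_locus={
                loc: d[sid] for loc, d in seqs_by_locus.items() if sid in d
            },
        )
        for sid in ids
    ]
    alignments = {
        loc: LocusAlignment(loc, [(sid, d[sid]) for sid in ids if sid in d])
        for loc, d in seqs_by_locus.items()
    }
    return MultiLocusDataset(specimens=specimens, alignments=alignments)


@pytest.fixture(scope="session")
def small_sim():
    """A small clean simulated dataset (no sharing/mislabels/dropout)."""
    cfg = SimulationConfig(
        seed=42,
        n_families=2,
        genera_per_family=2,
        species_per_genus=3,
        loci=[("matK", 400), ("rbcL", 300)],
        frac_shared_barcode=0.0,
        frac_mislabeled=0.0,
        dropout_by_locus={},
    )
    return simulate_dataset(cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_additive_matrix(n: int, rng: np.random.Generator):
    """Random unrooted binary tree with positive branch lengths.

    Returns (taxa, path-distance matrix, set of non-trivial splits normalized
    to the side excluding the lexicographically first taxon). Built by
    inserting leaves on random edges; distances are exact path sums, so the
    matrix is additive by construction.
    """
    import networkx as nx

    taxa = [f"t{i:02d}" for i in range(n)]
    G = nx.Graph()
    for t in taxa[:3]:
        G.add_edge(t, "i0", length=float(rng.uniform(0.05, 0.3)))
    nxt = 1
    for t in taxa[3:]:
        edges = sorted(G.edges(data=True))
        u, v, d = edges[rng.integers(len(edges))]
        G.remove_edge(u, v)
        mid = f"i{nxt}"
        nxt += 1
        a = float(rng.uniform(0.2, 0.8)) * d["length"]
        G.add_edge(u, mid, length=a)
        G.add_edge(mid, v, length=d["length"] - a)
        G.add_edge(t, mid, length=float(rng.uniform(0.05, 0.3)))
    paths = dict(nx.all_pairs_dijkstra_path_length(G, weight="length"))
    D = np.array([[paths[a][b] for b in taxa] for a in taxa])
    ref = min(taxa)
    splits = set()
    for u, v in G.edges():
        H = G.copy()
        H.remove_edge(u, v)
        comp = set(nx.node_connected_component(H, u))
        side = frozenset(t for t in taxa if t in comp)
        if 2 <= len(side) <= n - 2:
            splits.add(side if ref not in side else frozenset(taxa) - side)
    return taxa, D, splits


def simulated_alignment_on_random_tree(taxa, rng, L=200):
    """Sequences evolved down a random topology: a phylogenetically
    structured alignment (unlike iid noise, which has many parsimony optima)."""
    from barcode_eval.phylogeny import read_newick
    from barcode_eval.synthetic_data import (
        SimulationConfig,
        evolve_sequence,
        random_root_sequence,
    )

    cfg = SimulationConfig(seed=1)
    topologies = enumerate_unrooted_topologies(list(taxa))
    tree = read_newick(topologies[int(rng.integers(len(topologies)))], from_path=False)
    root = random_root_sequence(L, cfg, rng)
    seqs: dict[str, str] = {}
    rates = np.ones(L)

    def down(node, seq):
        for ch in node.child_nodes():
            s2 = evolve_sequence(seq, float(rng.uniform(0.05, 0.2)), cfg, rng, rates)
            if ch.is_leaf():
                seqs[ch.taxon.label] = s2
            else:
                down(ch, s2)

    down(tree.seed_node, root)
    return LocusAlignment("sim", [(t, seqs[t]) for t in taxa])


def enumerate_unrooted_topologies(taxa: list[str]):
    """All unrooted binary topologies as newick strings (15 for n=5, 105 for n=6).

    Trees are nested tuples with a 3-child top level; each new leaf is
    grafted onto every edge of every smaller tree.
    """

    def insert(tree, leaf):
        results = []

        def rec(node, rebuild):
            results.append(rebuild((node, leaf)))
            if not isinstance(node, str):
                for i, kid in enumerate(node):
                    rec(
                        kid,
                        lambda r, i=i, node=node, rebuild=rebuild: rebuild(
                            node[:i] + (r,) + node[i + 1:]
                        ),
                    )

        for i, kid in enumerate(tree):
            rec(kid, lambda r, i=i: tree[:i] + (r,) + tree[i + 1:])
        return results

    def render(t):
        if isinstance(t, str):
            return t
        return "(" + ",".join(render(k) for k in t) + ")"

    trees = [tuple(taxa[:3])]
    for leaf in taxa[3:]:
        trees = [t for tree in trees for t in insert(tree, leaf)]
    return [render(t) + ";" for t in trees]
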