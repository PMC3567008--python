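"""NJ reconstruction, bootstrap supports, rooting, monophyly, parsimony."""

import itertools

import dendropy
import numpy as np
import pytest

import cladegap as cg
from cladegap.distances import DistanceMatrix, distance_matrix
from cladegap.trees import (
    bootstrap,
    fitch_score,
    internal_splits,
    is_monophyletic,
    nj,
    node_support,
    root_with_outgroup,
    tree_tip_labels,
    _leafset,
)

from conftest import make_alignment


# ---------------------------------------------------------------------------
# helpers: random additive trees and their path-length matrices
# ---------------------------------------------------------------------------
def canonical_split(side, tipset):
    other = frozenset(tipset) - side
    return min(side, other, key=lambda s: (len(s), tuple(sorted(s))))


def family_alignment(rng, n, L, n_mut=4, prefix="s"):
    """Closely related sequences: one random base plus a few substitutions
    per row (keeps K2P far from saturation)."""
    base = rng.choice(list("ACGT"), L)
    rows = {}
    for i in range(n):
        seq = base.copy()
        pos = rng.integers(0, L, n_mut)
        for p in pos:
            seq[p] = "ACGT"[(("ACGT".index(seq[p])) + int(rng.integers(1, 4))) % 4]
        rows[f"{prefix}{i}"] = "".join(seq)
    return make_alignment(rows)


def random_additive_tree(rng, n):
    """Random binary topology with positive branch lengths; returns
    (ids, distance matrix, set of non-trivial splits as frozensets)."""
    ids = [f"t{i}" for i in range(n)]
    # start from a star over three nodes and attach remaining tips to a
    # random edge; track pairwise distances directly via a graph
    import networkx as nx

    g = nx.Graph()
    g.add_edge(ids[0], "root", weight=float(rng.uniform(0.1, 1.0)))
    g.add_edge(ids[1], "root", weight=float(rng.uniform(0.1, 1.0)))
    g.add_edge(ids[2], "root", weight=float(rng.uniform(0.1, 1.0)))
    inode = 0
    for tip in ids[3:]:
        u, v = list(g.edges())[rng.integers(0, g.number_of_edges())]
        w = g[u][v]["weight"]
        g.remove_edge(u, v)
        inode += 1
        mid = f"x{inode}"
        lam = float(rng.uniform(0.2, 0.8))
        g.add_edge(u, mid, weight=w * lam)
        g.add_edge(mid, v, weight=w * (1 - lam))
        g.add_edge(mid, tip, weight=float(rng.uniform(0.1, 1.0)))
    dist = dict(nx.all_pairs_dijkstra_path_length(g, weight="weight"))
    vals = np.array([[dist[a][b] for b in ids] for a in ids])
    # splits: removing each internal edge partitions the tips
    splits = set()
    for u, v in list(g.edges()):
        if u in ids or v in ids:
            continue
        h = g.copy()
        h.remove_edge(u, v)
        comp = set(next(c for c in nx.connected_components(h) if u in c))
        side = frozenset(t for t in ids if t in comp)
        if 1 < len(side) < n - 1:
            splits.add(canonical_split(side, ids))
    return ids, vals, splits


def splits_of(tree):
    tips = frozenset(tree_tip_labels(tree))
    out = set()
    for s in internal_splits(tree):
        a, _b = tuple(s)
        out.add(canonical_split(frozenset(a), tips))
    return out


class TestNeighborJoining:
    def test_worked_four_taxon_example(self):
        ids = ["A", "B", "C", "D"]
        vals = np.array(
            [[0, 5, 7, 8], [5, 0, 8, 9], [7, 8, 0, 9], [8, 9, 9, 0]], float
        )
        tree = nj(DistanceMatrix(ids, vals))
        assert splits_of(tree) == {frozenset({"A", "B"})}
        lengths = {}
        for lf in tree.leaf_node_iter():
            lengths[lf.taxon.label] = lf.edge.length
        assert lengths == pytest.approx({"A": 2, "B": 3, "C": 4, "D": 5})
        internal = [
            nd.edge.length
            for nd in tree.preorder_node_iter()
            if not nd.is_leaf() and nd.parent_node is not None
        ]
        assert internal == pytest.approx([1.0])

    def test_three_taxa_closed_form(self):
        vals = np.array([[0, 3, 4], [3, 0, 5], [4, 5, 0]], float)
        tree = nj(DistanceMatrix(["a", "b", "c"], vals))
        lengths = {lf.taxon.label: lf.edge.length for lf in tree.leaf_node_iter()}
        assert lengths == pytest.approx({"a": 1, "b": 2, "c": 3})

    def test_zero_matrix_gives_star(self):
        tree = nj(DistanceMatrix(list("abcd"), np.zeros((4, 4))))
        assert splits_of(tree) == set()
        assert all(lf.edge.length == 0 for lf in tree.leaf_node_iter())

    def test_exact_on_random_additive_matrices(self):
        rng = np.random.default_rng(17)
        for _ in range(25):
            n = int(rng.integers(4, 13))
            ids, vals, true_splits = random_additive_tree(rng, n)
            tree = nj(DistanceMatrix(ids, vals))
            assert splits_of(tree) == true_splits
            pdm = tree.phylogenetic_distance_matrix()
            taxa = {t.label: t for t in tree.taxon_namespace}
            for i, a in enumerate(ids):
                for b in ids[i + 1 :]:
                    got = pdm.patristic_distance(taxa[a], taxa[b])
                    want = vals[ids.index(a), ids.index(b)]
                    assert abs(got - want) < 1e-9

    def test_agrees_with_skbio_on_additive_matrix(self):
        # independent implementation cross-check on exact input
        from skbio import DistanceMatrix as SkDM
        from skbio.tree import nj as sk_nj

        rng = np.random.default_rng(23)
        ids, vals, true_splits = random_additive_tree(rng, 8)
        vals = (vals + vals.T) / 2  # exact symmetry for both consumers
        ours = splits_of(nj(DistanceMatrix(ids, vals)))
        sk_tree = sk_nj(SkDM(vals, ids))
        theirs = set()
        for node in sk_tree.non_tips(include_self=False):
            side = frozenset(t.name for t in node.tips())
            if 1 < len(side) < len(ids) - 1:
                theirs.add(canonical_split(side, ids))
        assert ours == theirs

    def test_na_entries_rejected_with_pair_names(self):
        vals = np.zeros((3, 3))
        vals[0, 1] = vals[1, 0] = np.nan
        with pytest.raises(ValueError, match="a.*b"):
            nj(DistanceMatrix(list("abc"), vals))


class TestBootstrap:
    def _two_cluster_alignment(self):
        rng = np.random.default_rng(1)
        base = rng.choice(list("ACGT"), 300)
        far = base.copy()
        far[:120] = np.where(far[:120] == "A", "C", "A")
        rows = {}
        for k, b in enumerate((base, far)):
            for j in range(2):
                seq = b.copy()
                pos = rng.integers(0, 300, 2)
                seq[pos] = "T"
                rows[f"g{k}_{j}"] = "".join(seq)
        return make_alignment(rows)

    def test_separated_clusters_get_full_support(self):
        aln = self._two_cluster_alignment()
        tree = bootstrap(aln, n_reps=100, seed=4)
        sups = [
            node_support(nd)
            for nd in tree.preorder_node_iter()
            if not nd.is_leaf() and nd.parent_node is not None
        ]
        assert sups and all(s == 100 for s in sups)

    def test_same_seed_reproduces_supports(self):
        aln = self._two_cluster_alignment()
        t1 = bootstrap(aln, n_reps=30, seed=9)
        t2 = bootstrap(aln, n_reps=30, seed=9)
        assert t1.as_string(schema="newick") == t2.as_string(schema="newick")

    def test_single_replicate_supports_are_all_or_nothing(self):
        rng = np.random.default_rng(2)
        tree = bootstrap(family_alignment(rng, 6, 80), n_reps=1, seed=3)
        sups = {
            node_support(nd)
            for nd in tree.preorder_node_iter()
            if not nd.is_leaf() and nd.parent_node is not None
        }
        assert sups <= {0, 100, None}

    def test_near_saturated_replicates_skipped_with_warning(self):
        # one pair sits close to the K2P singularity: many column
        # resamples cross it, and those replicates must be skipped,
        # counted, and warned about (>10%)
        L = 60
        n = int(0.45 * L)
        rows = {
            "a": "A" * L,
            "b": "G" * n + "A" * (L - n),
            "c": "A" * (L - 1) + "G",
            "d": "A" * (L - 2) + "GG",
        }
        with pytest.warns(RuntimeWarning, match="skipped"):
            tree = bootstrap(make_alignment(rows), n_reps=50, seed=2)
        assert tree.bootstrap_info.n_skipped > 5

    def test_supports_invariant_to_row_order(self):
        aln = self._two_cluster_alignment()
        rows = aln.rows
        rev = make_alignment({k: rows[k] for k in reversed(list(rows))})
        t1 = bootstrap(aln, n_reps=40, seed=6)
        t2 = bootstrap(rev, n_reps=40, seed=6)

        def support_map(t):
            tips = frozenset(tree_tip_labels(t))
            out = {}
            for nd in t.preorder_node_iter():
                if nd.is_leaf() or nd.parent_node is None:
                    continue
                side = frozenset(_leafset(nd))
                key = frozenset((side, tips - side))
                out[key] = node_support(nd)
            return out

        assert support_map(t1) == support_map(t2)


class TestRooting:
    def _tree(self):
        vals = np.array(
            [
                [0, 0.02, 0.30, 0.31],
                [0.02, 0, 0.30, 0.31],
                [0.30, 0.30, 0, 0.05],
                [0.31, 0.31, 0.05, 0],
            ]
        )
        return nj(DistanceMatrix(["x1", "x2", "y1", "og"], vals))

    def test_single_tip_outgroup(self):
        rooted = root_with_outgroup(self._tree(), {"og"})
        assert rooted.is_rooted
        kids = rooted.seed_node.child_nodes()
        assert len(kids) == 2
        sides = [_leafset(k) for k in kids]
        assert frozenset({"og"}) in sides

    def test_all_tips_outgroup_rejected(self):
        with pytest.raises(ValueError, match="every tip"):
            root_with_outgroup(self._tree(), {"x1", "x2", "y1", "og"})

    def test_non_clan_outgroup_rejected(self):
        with pytest.raises(ValueError, match="not separable"):
            root_with_outgroup(self._tree(), {"x1", "og"})

    def test_rerooting_is_idempotent(self):
        r1 = root_with_outgroup(self._tree(), {"og"})
        r2 = root_with_outgroup(r1, {"og"})
        assert internal_splits(r1) == internal_splits(r2)
        assert r1.as_string(schema="newick") == r2.as_string(schema="newick")

    def test_supports_carried_over(self):
        rng = np.random.default_rng(12)
        tree = bootstrap(family_alignment(rng, 7, 120, n_mut=8), n_reps=20, seed=5)
        before = {
            frozenset((frozenset(_leafset(n)), frozenset(tree_tip_labels(tree)) - frozenset(_leafset(n)))): node_support(n)
            for n in tree.preorder_node_iter()
            if not n.is_leaf() and n.parent_node is not None and node_support(n) is not None
        }
        rooted = root_with_outgroup(tree, {"s0"})
        after = {
            frozenset((frozenset(_leafset(n)), frozenset(tree_tip_labels(rooted)) - frozenset(_leafset(n)))): node_support(n)
            for n in rooted.preorder_node_iter()
            if not n.is_leaf() and n.parent_node is not None and node_support(n) is not None
        }
        # every pre-rooting split still present must keep its support
        shared = set(before) & set(after)
        assert shared
        for key in shared:
            assert after[key] == before[key]


class TestMonophyly:
    def _rooted(self):
        t = dendropy.Tree.get(
            data="((x1:1,x2:1)95:1,(y1:1,y2:1)88:1):0;",
            schema="newick",
            suppress_internal_node_taxa=True,
            preserve_underscores=True,
        )
        t.is_rooted = True
        return t

    def test_sister_pair(self):
        mono, sup = is_monophyletic(self._rooted(), {"x1", "x2"})
        assert mono and sup == 95

    def test_non_clade(self):
        mono, sup = is_monophyletic(self._rooted(), {"x1", "y1"})
        assert not mono and sup is None

    def test_singleton_convention(self):
        assert is_monophyletic(self._rooted(), {"x1"}) == (True, None)

    def test_unknown_tip_rejected(self):
        with pytest.raises(ValueError, match="unknown"):
            is_monophyletic(self._rooted(), {"zz"})

    def test_unrooted_tree_rejected(self):
        t = self._rooted()
        t.is_rooted = False
        with pytest.raises(ValueError, match="rooted"):
            is_monophyletic(t, {"x1", "x2"})


def brute_force_parsimony(newick, rows):
    """Minimum number of state changes over all internal assignments."""
    tree = dendropy.Tree.get(
        data=newick, schema="newick", suppress_internal_node_taxa=True,
        preserve_underscores=True,
    )
    tree.is_rooted = True
    nodes = list(tree.postorder_node_iter())
    internals = [n for n in nodes if not n.is_leaf()]
    L = len(next(iter(rows.values())))
    missing = set("-?N")
    total = 0
    for col in range(L):
        states = sorted({rows[k][col] for k in rows if rows[k][col] not in missing})
        if not states:
            continue
        best = None
        tips_free = [n for n in nodes if n.is_leaf() and rows[n.taxon.label][col] in missing]
        for assign in itertools.product(states, repeat=len(internals) + len(tips_free)):
            amap = {id(n): s for n, s in zip(internals + tips_free, assign)}
            cost = 0
            for n in nodes:
                if n.parent_node is None:
                    continue
                s_n = (
                    amap[id(n)]
                    if id(n) in amap
                    else rows[n.taxon.label][col]
                )
                s_p = amap[id(n.parent_node)]
                cost += s_n != s_p
            best = cost if best is None else min(best, cost)
        total += best
    return total


class TestFitchScore:
    def test_constant_alignment_costs_nothing(self):
        t = dendropy.Tree.get(data="((w,x),(y,z));", schema="newick")
        t.is_rooted = True
        aln = make_alignment({k: "AAAA" for k in "wxyz"})
        assert fitch_score(t, aln) == 0

    def test_hand_worked_column(self):
        aln = make_alignment({"w": "A", "x": "A", "y": "G", "z": "G"})
        t1 = dendropy.Tree.get(data="((w,x),(y,z));", schema="newick")
        t2 = dendropy.Tree.get(data="((w,y),(x,z));", schema="newick")
        for t in (t1, t2):
            t.is_rooted = True
        assert fitch_score(t1, aln) == 1
        assert fitch_score(t2, aln) == 2

    def test_matches_brute_force_enumeration(self):
        rng = np.random.default_rng(31)
        newick = "((a,b),(c,(d,e)));"
        for _ in range(10):
            rows = {
                k: "".join(rng.choice(list("ACGT-N"), 6, p=[0.2, 0.2, 0.2, 0.2, 0.1, 0.1]))
                for k in "abcde"
            }
            t = dendropy.Tree.get(data=newick, schema="newick")
            t.is_rooted = True
            assert fitch_score(t, make_alignment(rows)) == brute_force_parsimony(
                newick, rows
            )

    def test_binary_indel_characters_add_to_score(self):
        t = dendropy.Tree.get(data="((w,x),(y,z));", schema="newick")
        t.is_rooted = True
        aln = make_alignment({"w": "AAT", "x": "AAT", "y": "A-T", "z": "A-T"})
        coded = cg.simple_indel_coding(aln)
        assert coded.n_characters == 1
        # the gap column itself is ambiguous (missing), but the coded
        # presence/absence character adds exactly one change
        assert fitch_score(t, aln) == 0
        assert fitch_score(t, aln, indel_matrix=coded) == 1

    def test_star_tree_counts_variable_columns(self):
        t = dendropy.Tree.get(data="(a,b,c,d);", schema="newick")
        t.is_rooted = True
        rows = {"a": "AAG", "b": "ACG", "c": "AAG", "d": "AAG"}
        aln = make_alignment(rows)
        assert fitch_score(t, aln) == cg.variable_sites(aln)

    def test_tip_mismatch_rejected(self):
        t = dendropy.Tree.get(data="((w,x),(y,z));", schema="newick")
        t.is_rooted = True
        with pytest.raises(ValueError, match="match"):
            fitch_score(t, make_alignment({"w": "A", "x": "A"}))
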