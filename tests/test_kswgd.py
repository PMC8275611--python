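"""NG86 rates, family clustering, NJ trees, node weighting, peak detection."""

import itertools
import warnings

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import genodyn as g
from genodyn.io_core import HitRecord, SaturationError
from genodyn.kswgd import _STOPS, TreeNode


def _hit(q, s, e_value=1e-50, bit=200.0):
    return HitRecord(q, s, 90.0, 100, 5, 0, 1, 100, 1, 100, e_value, bit)


# ---------------------------------------------------------------------------
# NG86
# ---------------------------------------------------------------------------

def test_ng86_identical_sequences():
    assert g.ng86_rates("TTTGGGAAA", "TTTGGGAAA") == (0.0, 0.0)


def test_ng86_synonymous_difference():
    # one synonymous third-position change; S = 5/3 sites
    ka, ks = g.ng86_rates("TTTGGGAAA", "TTCGGGAAA")
    assert ka == pytest.approx(0.0)
    assert ks == pytest.approx(1.207, abs=1e-3)


def test_ng86_nonsynonymous_difference():
    # one first-position change F->V; S = 2, N = 7
    ka, ks = g.ng86_rates("TTTGGGAAA", "GTTGGGAAA")
    assert ks == pytest.approx(0.0)
    assert ka == pytest.approx(0.158, abs=1e-3)


def test_ng86_length_mismatch_errors():
    with pytest.raises(ValueError, match="length"):
        g.ng86_rates("TTTGGG", "TTT")


def test_ng86_internal_stop_errors():
    with pytest.raises(ValueError, match="stop"):
        g.ng86_rates("TTTTAAGGG", "TTTTAAGGG")


def test_ng86_skips_codons_with_n():
    ka, ks = g.ng86_rates("TTTNNNGGGAAA", "TTCNNNGGGAAA")
    assert ks > 0 and ka == pytest.approx(0.0)


def test_ng86_saturation_error():
    # every codon differs synonymously: Leu codons with huge divergence
    a = "CTT" * 30
    b = "TTA" * 30  # CTT->TTA is Leu->Leu via 2 changes, all-synonymous path
    with pytest.raises(SaturationError):
        g.ng86_rates(a, b)


def test_ng86_is_symmetric(rng):
    from genodyn.synthetic import random_cds
    for _ in range(5):
        a = random_cds(40, rng)
        b = g.evolve_sequence(a, 0.2, 2.0, rng)
        if any(b[3 * k: 3 * k + 3] in _STOPS for k in range(len(b) // 3)):
            continue
        assert g.ng86_rates(a, b) == g.ng86_rates(b, a)


def test_ng86_monotone_in_synonymous_changes():
    # adding third-position synonymous changes only ever raises Ks
    base = "TTTGGGAAACCCGAA" * 4
    prev_ks = 0.0
    seq = base
    syn_subs = [(2, "C"), (20, "A"), (38, "G")]  # TTT->TTC, GGG->GGA, AAA->AAG
    for pos, alt in syn_subs:
        seq = seq[:pos] + alt + seq[pos + 1:]
        ka, ks = g.ng86_rates(base, seq)
        assert ks > prev_ks and ka == pytest.approx(0.0)
        prev_ks = ks


def test_ng86_agrees_with_biopython_oracle(rng):
    """Independent cross-check on stop-free pathway cases."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        from Bio.codonalign.codonseq import CodonSeq, cal_dn_ds
    from genodyn.synthetic import random_cds

    def has_stop_pathway(a, b):
        for k in range(len(a) // 3):
            ca, cb = a[3 * k: 3 * k + 3], b[3 * k: 3 * k + 3]
            diff = [i for i in range(3) if ca[i] != cb[i]]
            for order in itertools.permutations(diff):
                cur = ca
                for pos in order[:-1]:
                    cur = cur[:pos] + cb[pos] + cur[pos + 1:]
                    if cur in _STOPS:
                        return True
        return False

    checked = 0
    while checked < 10:
        a = random_cds(30, rng)
        b = g.evolve_sequence(a, 0.3, 2.0, rng)
        if any(b[3 * k: 3 * k + 3] in _STOPS for k in range(len(b) // 3)):
            continue
        if has_stop_pathway(a, b):
            continue
        try:
            dn, ds = cal_dn_ds(CodonSeq(a), CodonSeq(b), method="NG86")
            ka, ks = g.ng86_rates(a, b)
        except (SaturationError, ValueError, KeyError):
            continue
        assert ka == pytest.approx(dn, abs=1e-9)
        assert ks == pytest.approx(ds, abs=1e-9)
        checked += 1


# ---------------------------------------------------------------------------
# Families
# ---------------------------------------------------------------------------

def test_cluster_two_disjoint_triangles():
    hits = [_hit(a, b) for tri in (("A", "B", "C"), ("X", "Y", "Z"))
            for a, b in itertools.combinations(tri, 2)]
    for method in ("components", "markov"):
        fams = g.cluster_families(hits, method=method)
        assert [f for f in fams if len(f) > 1] == [["A", "B", "C"], ["X", "Y", "Z"]]


def test_cluster_evalue_cutoff_splits_chain():
    hits = [_hit("A", "B", e_value=1e-40), _hit("B", "C", e_value=1e-5)]
    fams = g.cluster_families(hits, e_value_cutoff=1e-10)
    assert fams == [["A", "B"], ["C"]]


def test_cluster_markov_splits_barbell():
    """Two 4-cliques joined by one edge separate at inflation 1.5."""
    left, right = list("ABCD"), list("EFGH")
    hits = [_hit(a, b) for grp in (left, right)
            for a, b in itertools.combinations(grp, 2)]
    hits.append(_hit("D", "E"))
    fams = g.cluster_families(hits, method="markov", inflation=1.5)
    big = [f for f in fams if len(f) > 1]
    assert big == [left, right]


def test_cluster_unknown_method_errors():
    with pytest.raises(ValueError):
        g.cluster_families([_hit("A", "B")], method="magic")


@pytest.mark.parametrize(
    "edges,expected",
    [
        ({("A", "B"): 1.0, ("B", "C"): 2.0, ("A", "C"): 4.9}, [["A", "B", "C"]]),
        ({("A", "B"): 1.0, ("C", "D"): 1.0, ("B", "C"): 6.0},
         [["A", "B"], ["C", "D"]]),
    ],
)
def test_subdivide_by_ks(edges, expected):
    genes = sorted({x for e in edges for x in e})
    assert g.subdivide_by_ks(genes, edges, threshold=5.0) == expected


def test_subdivide_drops_singletons():
    assert g.subdivide_by_ks(["A"], {}) == []
    assert g.subdivide_by_ks(["A", "B"], {("A", "B"): None}) == []  # saturated


# ---------------------------------------------------------------------------
# Neighbor joining
# ---------------------------------------------------------------------------

def test_nj_two_taxa_symmetric_split():
    tree = g.nj_tree(np.array([[0, 0.8], [0.8, 0]]), ["A", "B"])
    left, right = tree.root.children
    assert {left.name, right.name} == {"A", "B"}
    assert left.branch_length == right.branch_length == pytest.approx(0.4)


def test_nj_three_taxa_tie_breaks_to_first_pair():
    D = np.array([[0, 0.2, 1.0], [0.2, 0, 1.0], [1.0, 1.0, 0]])
    tree = g.nj_tree(D, ["A", "B", "C"])
    cherries = [set(c.leaves()) for c in tree.root.children]
    assert {"A", "B"} in cherries


def test_nj_recovers_additive_four_taxon_tree():
    # true tree: ((A:1,B:2):3,(C:4,D:5)) with internal edge 3
    D = np.zeros((4, 4))
    path = {
        ("A", "B"): 3, ("A", "C"): 8, ("A", "D"): 9,
        ("B", "C"): 9, ("B", "D"): 10, ("C", "D"): 9,
    }
    labels = ["A", "B", "C", "D"]
    for (x, y), d in path.items():
        i, j = labels.index(x), labels.index(y)
        D[i, j] = D[j, i] = d
    tree = g.nj_tree(D, labels)
    groups = sorted(sorted(c.leaves()) for c in tree.root.children)
    assert groups == [["A", "B"], ["C", "D"]]
    # leaf branch lengths recovered exactly
    lengths = {}
    def walk(node):
        if not node.children:
            lengths[node.name] = node.branch_length
        for c in node.children:
            walk(c)
    walk(tree.root)
    assert lengths == pytest.approx({"A": 1, "B": 2, "C": 4, "D": 5})
    # the internal edge is split across the root's two children
    internal = sum(c.branch_length for c in tree.root.children)
    assert internal == pytest.approx(3)


def test_nj_rejects_single_taxon():
    with pytest.raises(ValueError):
        g.nj_tree(np.zeros((1, 1)), ["A"])


# ---------------------------------------------------------------------------
# Node weighting
# ---------------------------------------------------------------------------

def test_node_weights_pair():
    tree = g.nj_tree(np.array([[0, 1.0], [1.0, 0]]), ["A", "B"])
    (est,) = g.node_weighted_ks(tree, {("A", "B"): 1.0})
    assert est.weight == 1.0 and est.ks == 1.0


def test_node_weights_three_leaf_tree():
    D = np.array([[0, 0.2, 1.0], [0.2, 0, 1.0], [1.0, 1.0, 0]])
    tree = g.nj_tree(D, ["A", "B", "C"])
    ks = {("A", "B"): 0.2, ("A", "C"): 1.0, ("B", "C"): 1.0}
    weights = {
        tuple(sorted((e.gene_a, e.gene_b))): e.weight
        for e in g.node_weighted_ks(tree, ks)
    }
    assert weights == {("A", "B"): 1.0, ("A", "C"): 0.5, ("B", "C"): 0.5}


def _random_binary_tree(labels, rng) -> TreeNode:
    nodes = [TreeNode(name=l) for l in labels]
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        merged = TreeNode(children=[nodes[i], nodes[j]])
        nodes = [n for k, n in enumerate(nodes) if k not in (i, j)] + [merged]
    return nodes[0]


def test_node_weights_sum_to_n_minus_one_on_random_trees(rng):
    """Enumeration oracle: every leaf pair contributes once, at the node that
    is its join, with weight 1 / (cross-pair count); totals are n - 1."""
    from genodyn.kswgd import FamilyTree

    for trial in range(200):
        n = int(rng.integers(2, 9))
        labels = [f"g{k}" for k in range(n)]
        tree = FamilyTree(root=_random_binary_tree(labels, rng))
        ks = {pair: 1.0 for pair in itertools.combinations(labels, 2)}
        estimates = g.node_weighted_ks(tree, dict(ks))
        assert len(estimates) == n * (n - 1) // 2
        total = sum(e.weight for e in estimates)
        assert total == pytest.approx(n - 1, abs=1e-9)
        # oracle: expected weight per pair from the tree structure itself
        expected = {}
        for node in tree.duplication_nodes():
            left, right = (set(c.leaves()) for c in node.children)
            m = len(left) * len(right)
            for a in left:
                for b in right:
                    key = tuple(sorted((a, b)))
                    assert key not in expected  # each pair crosses one node
                    expected[key] = 1.0 / m
        got = {tuple(sorted((e.gene_a, e.gene_b))): e.weight for e in estimates}
        assert got == pytest.approx(expected)


def test_node_weights_missing_pair_errors():
    tree = g.nj_tree(np.array([[0, 1.0], [1.0, 0]]), ["A", "B"])
    with pytest.raises(KeyError, match="A.*B"):
        g.node_weighted_ks(tree, {})


def test_newick_round_trip(tmp_path):
    D = np.array([[0, 0.2, 1.0], [0.2, 0, 1.0], [1.0, 1.0, 0]])
    tree = g.nj_tree(D, ["A", "B", "C"])
    path = tmp_path / "t.nwk"
    g.write_newick(tree, path)
    back = g.read_newick(path)
    assert sorted(back.leaves()) == ["A", "B", "C"]
    assert [set(c.leaves()) for c in back.root.children] == [
        set(c.leaves()) for c in tree.root.children
    ]

    def lengths(node, acc):
        if not node.children:
            acc[node.name] = node.branch_length
        for c in node.children:
            lengths(c, acc)
        return acc

    assert lengths(back.root, {}) == pytest.approx(lengths(tree.root, {}))


# ---------------------------------------------------------------------------
# RBH orthologs
# ---------------------------------------------------------------------------

def test_rbh_mutual_best_kept():
    ab = [_hit("a1", "b1", bit=300), _hit("a1", "b2", bit=100)]
    ba = [_hit("b1", "a1", bit=290), _hit("b2", "a1", bit=90)]
    assert g.rbh_orthologs(ab, ba) == [("a1", "b1")]


def test_rbh_non_reciprocal_excluded():
    ab = [_hit("a1", "b1", bit=300)]
    ba = [_hit("b1", "a2", bit=290)]
    assert g.rbh_orthologs(ab, ba) == []


def test_rbh_tie_breaks_deterministically():
    ab = [_hit("a1", "b2", bit=300), _hit("a1", "b1", bit=300)]
    ba = [_hit("b1", "a1", bit=300), _hit("b2", "a1", bit=300)]
    # tie on bit score and e-value -> lexicographically smaller subject wins
    assert g.rbh_orthologs(ab, ba) == [("a1", "b1")]


# ---------------------------------------------------------------------------
# Peak detection and the dating window
# ---------------------------------------------------------------------------

def test_peak_on_gaussian_sample():
    rng = np.random.default_rng(3)
    values = rng.normal(1.0, 0.15, 1000)
    values = values[values > 0]
    calls = g.detect_ks_peaks(values, seed=3)
    assert 0.9 <= calls[0].location <= 1.1
    assert calls[0].ci_low <= calls[0].location <= calls[0].ci_high


def test_peak_requires_enough_values():
    with pytest.raises(ValueError):
        g.detect_ks_peaks([1.0] * 10, seed=0)


def test_peaks_recover_balanced_mixture():
    rng = np.random.default_rng(4)
    values = np.concatenate([
        rng.normal(0.5, 0.1, 500), rng.normal(2.0, 0.1, 500)
    ])
    calls = g.detect_ks_peaks(values[values > 0], seed=4)
    locs = sorted(c.location for c in calls[:2])
    assert locs[0] == pytest.approx(0.5, abs=0.1)
    assert locs[1] == pytest.approx(2.0, abs=0.1)


@pytest.mark.parametrize("ks,kept", [(0.9, True), (0.5, False), (1.25, True),
                                     (0.7, True), (1.26, False)])
def test_select_dating_window(ks, kept):
    est = g.KsEstimate("a", "b", ks=ks)
    selected = g.select_dating_window([est])
    assert (len(selected) == 1) is kept


def test_select_dating_window_rejects_inverted_bounds():
    with pytest.raises(ValueError):
        g.select_dating_window([], low=2.0, high=1.0)
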