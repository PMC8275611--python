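"""Redundancy-corrected Ks age distributions and WGD peak detection.

A whole-genome duplication leaves a burst of paralog pairs sharing a common
synonymous divergence, visible as a peak in the distribution of Ks
(synonymous substitutions per synonymous site) over the paranome.  Naive
all-pairs distributions overweight large families: a family of n genes
contributes n(n-1)/2 pairs for only n-1 duplication events.  Here each
duplication node of a subfamily tree contributes total weight one, spread
as 1/m over its m cross-clade pairs, so the weighted distribution counts
duplication events rather than gene pairs.

Ks itself is estimated by Nei-Gojobori (1986) counting with Jukes-Cantor
correction; families come from the similarity-hit graph (connected
components or Markov clustering), subfamily trees from neighbor joining on
Ks distances, and peaks from a weighted Gaussian KDE with bootstrap
percentile confidence intervals.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

from pathlib import Path

import dendropy
import networkx as nx
import numpy as np
from Bio.Data import CodonTable
from scipy import signal, stats

from .io_core import HitRecord, SaturationError, get_logger

__all__ = [
    "KsEstimate",
    "TreeNode",
    "FamilyTree",
    "PeakCall",
    "ng86_rates",
    "cluster_families",
    "subdivide_by_ks",
    "nj_tree",
    "node_weighted_ks",
    "rbh_orthologs",
    "read_newick",
    "write_newick",
    "detect_ks_peaks",
    "select_dating_window",
    "weighted_ks_distribution",
]

_LOG = get_logger("genodyn.ks")

_TABLE = CodonTable.unambiguous_dna_by_id[1]
_STOPS = set(_TABLE.stop_codons)
_BASES = "ACGT"


def _translate(codon: str) -> str | None:
    """Amino acid for a codon; None for stops."""
    if codon in _STOPS:
        return None
    return _TABLE.forward_table[codon]


# ---------------------------------------------------------------------------
# Nei-Gojobori (1986) Ka/Ks
# ---------------------------------------------------------------------------

def _syn_sites(codon: str) -> float:
    """Synonymous site count of a codon: per position, the fraction of the
    three possible changes that preserve the amino acid (changes to stop
    codons count as nonsynonymous)."""
    aa = _translate(codon)
    s = 0.0
    for pos in range(3):
        syn = 0
        for base in _BASES:
            if base == codon[pos]:
                continue
            alt = codon[:pos] + base + codon[pos + 1:]
            if alt not in _STOPS and _translate(alt) == aa:
                syn += 1
        s += syn / 3.0
    return s


def _pathway_counts(codon_a: str, codon_b: str) -> tuple[float, float]:
    """Observed synonymous / nonsynonymous differences between two codons,
    averaged over equal-weight minimal mutational pathways.

    Pathways passing through a stop codon are excluded; if every pathway is
    blocked, all are used with steps to/from stops counted nonsynonymous.
    """
    diff_pos = [i for i in range(3) if codon_a[i] != codon_b[i]]
    if not diff_pos:
        return 0.0, 0.0

    def walk(order: tuple[int, ...], allow_stops: bool) -> tuple[float, float] | None:
        sd = nd = 0.0
        current = codon_a
        for pos in order:
            nxt = current[:pos] + codon_b[pos] + current[pos + 1:]
            if nxt in _STOPS and nxt != codon_b and not allow_stops:
                return None
            aa_from, aa_to = _translate(current), _translate(nxt)
            if aa_from is not None and aa_from == aa_to:
                sd += 1.0
            else:
                nd += 1.0
            current = nxt
        return sd, nd

    orders = list(itertools.permutations(diff_pos))
    results = [r for order in orders if (r := walk(order, False)) is not None]
    if not results:
        results = [walk(order, True) for order in orders]
    sd = sum(r[0] for r in results) / len(results)
    nd = sum(r[1] for r in results) / len(results)
    return sd, nd


def _jc_correct(p: float, label: str) -> float:
    if p >= 0.75:
        raise SaturationError(f"{label} saturated: proportion {p:.4f} >= 3/4")
    return -0.75 * math.log(1.0 - (4.0 / 3.0) * p)


def ng86_rates(cds_a: str, cds_b: str) -> tuple[float, float]:
    """Nonsynonymous (Ka) and synonymous (Ks) substitution rates by
    Nei-Gojobori counting with Jukes-Cantor correction.

    Sequences must be equal-length in-frame CDS without internal stop
    codons; codons containing N (and a shared terminal stop) are skipped.
    Raises :class:`SaturationError` when a corrected rate is undefined.
    """
    if len(cds_a) != len(cds_b):
        raise ValueError(
            f"CDS length mismatch: {len(cds_a)} vs {len(cds_b)}"
        )
    if len(cds_a) % 3 != 0:
        raise ValueError(f"CDS length {len(cds_a)} is not a multiple of 3")
    cds_a, cds_b = cds_a.upper(), cds_b.upper()
    n_codons = len(cds_a) // 3
    S = 0.0
    sites_total = 0
    sd = nd = 0.0
    for k in range(n_codons):
        ca, cb = cds_a[3 * k: 3 * k + 3], cds_b[3 * k: 3 * k + 3]
        if "N" in ca or "N" in cb:
            continue
        if ca in _STOPS or cb in _STOPS:
            if k == n_codons - 1 and ca in _STOPS and cb in _STOPS:
                continue  # shared terminal stop codon
            raise ValueError(f"internal stop codon at codon {k + 1}")
        S += (_syn_sites(ca) + _syn_sites(cb)) / 2.0
        sites_total += 3
        d_s, d_n = _pathway_counts(ca, cb)
        sd += d_s
        nd += d_n
    if sites_total == 0:
        raise ValueError("no comparable codons")
    N = sites_total - S
    ps = sd / S if S > 0 else 0.0
    pn = nd / N if N > 0 else 0.0
    ka = _jc_correct(pn, "ka")
    ks = _jc_correct(ps, "ks")
    return ka, ks


# ---------------------------------------------------------------------------
# Gene families
# ---------------------------------------------------------------------------

def cluster_families(
    hits: Sequence[HitRecord],
    e_value_cutoff: float = 1e-10,
    method: str = "components",
    inflation: float = 1.5,
) -> list[list[str]]:
    """Gene families from the similarity-hit graph.

    Edges with e-value above the cutoff are dropped.  ``components`` takes
    connected components; ``markov`` runs Markov clustering (expansion =
    matrix square, inflation = element-wise power, column renormalization,
    iterated to a fixed point) on the -log10(e-value) similarity matrix.
    Families are returned sorted, singletons included.
    """
    genes = sorted({h.query_id for h in hits} | {h.subject_id for h in hits})
    edges: dict[tuple[str, str], float] = {}
    for h in hits:
        if h.query_id == h.subject_id or h.e_value > e_value_cutoff:
            continue
        key = tuple(sorted((h.query_id, h.subject_id)))
        sim = -math.log10(max(h.e_value, 1e-180))
        edges[key] = max(edges.get(key, 0.0), sim)

    if method == "components":
        graph = nx.Graph()
        graph.add_nodes_from(genes)
        graph.add_edges_from(edges)
        return sorted(sorted(c) for c in nx.connected_components(graph))
    if method != "markov":
        raise ValueError(f"unknown clustering method {method!r}")

    index = {g: i for i, g in enumerate(genes)}
    n = len(genes)
    M = np.zeros((n, n))
    for (a, b), sim in edges.items():
        M[index[a], index[b]] = sim
        M[index[b], index[a]] = sim
    col_sums = M.sum(axis=0)
    col_sums[col_sums == 0] = 1.0
    M = M / col_sums
    for _ in range(200):
        expanded = M @ M
        inflated = expanded ** inflation
        sums = inflated.sum(axis=0)
        sums[sums == 0] = 1.0
        new = inflated / sums
        if np.abs(new - M).max() < 1e-10:
            M = new
            break
        M = new
    eps = 1e-6
    clusters: list[set[str]] = []
    for i in range(n):
        if M[i, i] > eps:  # attractor row: its support is a cluster
            support = {genes[j] for j in np.nonzero(M[i] > eps)[0]}
            support.add(genes[i])
            for c in clusters:
                if c & support:
                    c |= support
                    break
            else:
                clusters.append(support)
    assigned = set().union(*clusters) if clusters else set()
    clusters.extend({g} for g in genes if g not in assigned)
    return sorted(sorted(c) for c in clusters)


def subdivide_by_ks(
    family: Sequence[str],
    ks_lookup: Mapping[tuple[str, str], float | None],
    threshold: float = 5.0,
) -> list[list[str]]:
    """Split a family into subfamilies connected by pairwise Ks <= threshold.

    Saturated pairs (value None) count as exceeding the threshold.  Genes
    left without any retained edge (including singleton input) are dropped.
    """
    graph = nx.Graph()
    graph.add_nodes_from(family)
    for a, b in itertools.combinations(sorted(family), 2):
        ks = ks_lookup.get((a, b), ks_lookup.get((b, a)))
        if ks is not None and ks <= threshold:
            graph.add_edge(a, b)
    return sorted(
        sorted(c) for c in nx.connected_components(graph) if len(c) >= 2
    )


# ---------------------------------------------------------------------------
# Neighbor joining and node weighting
# ---------------------------------------------------------------------------

@dataclass
class TreeNode:
    name: str | None = None
    children: list["TreeNode"] = field(default_factory=list)
    branch_length: float = 0.0

    def leaves(self) -> list[str]:
        if not self.children:
            return [self.name]  # type: ignore[list-item]
        out: list[str] = []
        for child in self.children:
            out.extend(child.leaves())
        return out

    def internal_nodes(self) -> list["TreeNode"]:
        out: list[TreeNode] = []
        if self.children:
            out.append(self)
            for child in self.children:
                out.extend(child.internal_nodes())
        return out

    def to_newick(self) -> str:
        def fmt(node: TreeNode) -> str:
            if not node.children:
                return f"{node.name}:{node.branch_length:.6g}"
            inner = ",".join(fmt(c) for c in node.children)
            return f"({inner}):{node.branch_length:.6g}"

        return fmt(self).rsplit(":", 1)[0] + ";"


@dataclass
class FamilyTree:
    """Rooted binary subfamily tree; n leaves, n-1 duplication nodes."""

    root: TreeNode
    family_id: str = ""

    def leaves(self) -> list[str]:
        return self.root.leaves()

    def duplication_nodes(self) -> list[TreeNode]:
        return self.root.internal_nodes()


def nj_tree(
    distance: np.ndarray,
    labels: Sequence[str],
    family_id: str = "",
) -> FamilyTree:
    """Neighbor joining on a symmetric non-negative distance matrix.

    Ties on the Q criterion break to the lowest index pair in the current
    agglomeration order, so the result is deterministic.  The final join of
    the last two clusters roots the tree (each child gets half the
    remaining distance), giving exactly n-1 internal nodes for weighting.
    """
    n = len(labels)
    if n < 2:
        raise ValueError("neighbor joining needs at least 2 taxa")
    D = np.asarray(distance, dtype=float).copy()
    if D.shape != (n, n):
        raise ValueError("distance matrix shape does not match labels")
    if not np.allclose(D, D.T):
        raise ValueError("distance matrix is not symmetric")
    nodes: list[TreeNode] = [TreeNode(name=lbl) for lbl in labels]
    active = list(range(n))

    while len(active) > 2:
        k = len(active)
        r = {i: sum(D[i, j] for j in active if j != i) for i in active}
        best = None
        for ai in range(k):
            for aj in range(ai + 1, k):
                i, j = active[ai], active[aj]
                q = (k - 2) * D[i, j] - r[i] - r[j]
                if best is None or q < best[0] - 1e-12:
                    best = (q, ai, aj)
        _, ai, aj = best  # type: ignore[misc]
        i, j = active[ai], active[aj]
        li = 0.5 * D[i, j] + (r[i] - r[j]) / (2.0 * (k - 2))
        lj = D[i, j] - li
        nodes[i].branch_length = li
        nodes[j].branch_length = lj
        parent = TreeNode(children=[nodes[i], nodes[j]])
        # reuse slot i for the new cluster, grow D by appending? simpler: new row
        new_idx = D.shape[0]
        col = np.zeros((new_idx, 1))
        D = np.vstack((np.hstack((D, col)), np.zeros((1, new_idx + 1))))
        for m in active:
            if m in (i, j):
                continue
            d = 0.5 * (D[i, m] + D[j, m] - D[i, j])
            D[new_idx, m] = D[m, new_idx] = d
        nodes.append(parent)
        active = [m for m in active if m not in (i, j)] + [new_idx]

    i, j = active
    half = D[i, j] / 2.0
    nodes[i].branch_length = half
    nodes[j].branch_length = half
    root = TreeNode(children=[nodes[i], nodes[j]])
    return FamilyTree(root=root, family_id=family_id)


@dataclass
class KsEstimate:
    gene_a: str
    gene_b: str
    ks: float
    ka: float = 0.0
    weight: float = 1.0
    family_id: str = ""
    node_id: int | None = None


def node_weighted_ks(
    tree: FamilyTree,
    ks_lookup: Mapping[tuple[str, str], float | None],
    ka_lookup: Mapping[tuple[str, str], float] | None = None,
) -> list[KsEstimate]:
    """Attach 1/m weights to pairwise Ks estimates by duplication node.

    Every leaf pair crosses exactly one internal node; a node separating
    clades of sizes p and q has m = p*q cross pairs, each weighted 1/m so
    the node's total weight is one.  Saturated pairs (lookup value None)
    contribute no estimate but still count toward m.
    """
    def get(mapping, a, b):
        key = (a, b) if (a, b) in mapping else (b, a)
        if key not in mapping:
            raise KeyError(f"missing Ks for pair ({a}, {b})")
        return mapping[key]

    estimates: list[KsEstimate] = []
    for node_id, node in enumerate(tree.duplication_nodes()):
        left, right = node.children[0].leaves(), node.children[1].leaves()
        m = len(left) * len(right)
        for a in left:
            for b in right:
                ks = get(ks_lookup, a, b)
                if ks is None:
                    continue  # saturated: excluded from the distribution
                ka = get(ka_lookup, a, b) if ka_lookup else 0.0
                ga, gb = sorted((a, b))
                estimates.append(
                    KsEstimate(
                        gene_a=ga, gene_b=gb, ks=ks, ka=ka,
                        weight=1.0 / m, family_id=tree.family_id,
                        node_id=node_id,
                    )
                )
    return estimates


def write_newick(tree: FamilyTree, path) -> None:
    """Write a subfamily tree as Newick."""
    Path(path).write_text(tree.root.to_newick() + "\n")


def read_newick(path, family_id: str = "") -> FamilyTree:
    """Read a rooted tree from Newick (parsed by dendropy)."""
    dtree = dendropy.Tree.get(path=str(path), schema="newick")

    def convert(dnode) -> TreeNode:
        node = TreeNode(
            name=dnode.taxon.label if dnode.taxon else None,
            branch_length=float(dnode.edge.length or 0.0),
        )
        node.children = [convert(c) for c in dnode.child_nodes()]
        return node

    return FamilyTree(root=convert(dtree.seed_node), family_id=family_id)


# ---------------------------------------------------------------------------
# Reciprocal best hits
# ---------------------------------------------------------------------------

def _best_hits(hits: Sequence[HitRecord]) -> dict[str, str]:
    best: dict[str, HitRecord] = {}
    for h in hits:
        cur = best.get(h.query_id)
        if cur is None:
            best[h.query_id] = h
            continue
        key_new = (-h.bit_score, h.e_value, h.subject_id)
        key_cur = (-cur.bit_score, cur.e_value, cur.subject_id)
        if key_new < key_cur:
            best[h.query_id] = h
        elif key_new[:2] == key_cur[:2] and h.subject_id != cur.subject_id:
            _LOG.info(
                "RBH tie for %s: kept %s over %s",
                h.query_id, min(h.subject_id, cur.subject_id),
                max(h.subject_id, cur.subject_id),
            )
    return {q: h.subject_id for q, h in best.items()}


def rbh_orthologs(
    hits_ab: Sequence[HitRecord],
    hits_ba: Sequence[HitRecord],
) -> list[tuple[str, str]]:
    """One-to-one ortholog pairs by reciprocal best hit.

    Best hits rank by bit score, then lower e-value, then lexicographic
    subject id (deterministic tie-break, logged).
    """
    best_ab = _best_hits(hits_ab)
    best_ba = _best_hits(hits_ba)
    pairs = [
        (a, b) for a, b in best_ab.items() if best_ba.get(b) == a
    ]
    return sorted(pairs)


# ---------------------------------------------------------------------------
# Peak detection
# ---------------------------------------------------------------------------

@dataclass
class PeakCall:
    location: float
    height: float
    ci_low: float
    ci_high: float
    n_bootstrap: int


def _weighted_kde(values: np.ndarray, weights: np.ndarray, bandwidth: float | None):
    if bandwidth is None:
        return stats.gaussian_kde(values, weights=weights, bw_method="silverman")
    mean = np.average(values, weights=weights)
    var = np.average((values - mean) ** 2, weights=weights)
    std = math.sqrt(var) if var > 0 else 1.0
    return stats.gaussian_kde(values, weights=weights, bw_method=bandwidth / std)


def _find_density_peaks(
    grid: np.ndarray, density: np.ndarray, prominence_frac: float
) -> list[tuple[float, float]]:
    """(location, height) of local maxima above a fraction of the global max,
    tallest first."""
    floor = prominence_frac * density.max()
    idx, _props = signal.find_peaks(density, height=floor)
    peaks = [(float(grid[i]), float(density[i])) for i in idx]
    if not peaks:  # maximum at a grid boundary
        i = int(np.argmax(density))
        peaks = [(float(grid[i]), float(density[i]))]
    return sorted(peaks, key=lambda p: -p[1])


def detect_ks_peaks(
    values: Sequence[float],
    weights: Sequence[float] | None = None,
    bandwidth: float | None = None,
    ks_range: tuple[float, float] = (0.05, 5.0),
    n_bootstrap: int = 200,
    seed: int = 0,
    prominence_frac: float = 0.10,
    ci_level: float = 0.90,
    min_values: int = 30,
) -> list[PeakCall]:
    """WGD peaks of the weighted Ks distribution.

    Weighted Gaussian KDE (Silverman bandwidth by default) over values
    inside ``ks_range`` (floor excluded, ceiling included); peaks are local
    density maxima above ``prominence_frac`` of the global maximum.
    Confidence bounds are percentiles of matched peak locations over
    weighted bootstrap resamples.  Peaks are returned tallest first.
    """
    values = np.asarray(values, dtype=float)
    weights = (
        np.ones_like(values) if weights is None else np.asarray(weights, dtype=float)
    )
    low, high = ks_range
    mask = (values > low) & (values <= high)
    values, weights = values[mask], weights[mask]
    if values.size < min_values:
        raise ValueError(
            f"need >= {min_values} weighted Ks values in range, got {values.size}"
        )
    probs = weights / weights.sum()
    grid = np.linspace(low, high, 512)
    kde = _weighted_kde(values, weights, bandwidth)
    density = kde(grid)
    peaks = _find_density_peaks(grid, density, prominence_frac)

    rng = np.random.default_rng(seed)
    boot_locs: list[list[float]] = [[] for _ in peaks]
    for _ in range(n_bootstrap):
        idx = rng.choice(values.size, size=values.size, replace=True, p=probs)
        sample = values[idx]
        if np.ptp(sample) <= 0:
            continue
        b_kde = _weighted_kde(sample, np.ones_like(sample), bandwidth)
        b_peaks = _find_density_peaks(grid, b_kde(grid), prominence_frac)
        for p_i, (loc, _h) in enumerate(peaks):
            nearest = min(b_peaks, key=lambda p: abs(p[0] - loc))
            boot_locs[p_i].append(nearest[0])

    tail = (1.0 - ci_level) / 2.0 * 100.0
    calls: list[PeakCall] = []
    for (loc, height), locs in zip(peaks, boot_locs):
        if locs:
            lo, hi = np.percentile(locs, [tail, 100.0 - tail])
        else:
            lo = hi = loc
        calls.append(
            PeakCall(
                location=loc, height=height,
                ci_low=min(float(lo), loc), ci_high=max(float(hi), loc),
                n_bootstrap=len(locs),
            )
        )
    return calls


def weighted_ks_distribution(
    cds_by_gene: Mapping[str, str],
    hits: Sequence[HitRecord],
    e_value_cutoff: float = 1e-10,
    method: str = "components",
    subfamily_threshold: float = 5.0,
    saturated_cap: float = 10.0,
) -> list[KsEstimate]:
    """End-to-end node-weighted paranome Ks distribution.

    Families from the hit graph, pairwise NG86 Ks within families,
    Ks-threshold subfamilies, an NJ tree per subfamily, and 1/m weights per
    duplication node.  Saturated pairs enter NJ at ``saturated_cap`` but
    contribute no estimate.
    """
    families = cluster_families(hits, e_value_cutoff=e_value_cutoff, method=method)
    estimates: list[KsEstimate] = []
    n_saturated = 0
    for f_idx, family in enumerate(families):
        family = [g for g in family if g in cds_by_gene]
        if len(family) < 2:
            continue
        ks_lookup: dict[tuple[str, str], float | None] = {}
        ka_lookup: dict[tuple[str, str], float] = {}
        for a, b in itertools.combinations(sorted(family), 2):
            try:
                ka, ks = ng86_rates(cds_by_gene[a], cds_by_gene[b])
            except SaturationError:
                ka, ks = 0.0, None
                n_saturated += 1
            ks_lookup[(a, b)] = ks
            ka_lookup[(a, b)] = ka
        for s_idx, subfamily in enumerate(
            subdivide_by_ks(family, ks_lookup, threshold=subfamily_threshold)
        ):
            n = len(subfamily)
            D = np.zeros((n, n))
            for i in range(n):
                for j in range(i + 1, n):
                    key = (subfamily[i], subfamily[j])
                    ks = ks_lookup.get(key, ks_lookup.get(key[::-1]))
                    D[i, j] = D[j, i] = saturated_cap if ks is None else ks
            tree = nj_tree(D, subfamily, family_id=f"F{f_idx}.{s_idx}")
            estimates.extend(node_weighted_ks(tree, ks_lookup, ka_lookup))
    _LOG.info(
        "paranome: %d families, %d weighted estimates, %d saturated pairs",
        len(families), len(estimates), n_saturated,
    )
    return estimates


def select_dating_window(
    estimates: Sequence[KsEstimate],
    low: float = 0.7,
    high: float = 1.25,
) -> list[KsEstimate]:
    """Duplicates inside the Ks window used for absolute dating (inclusive)."""
    if low > high:
        raise ValueError(f"window low {low} > high {high}")
    return [e for e in estimates if low <= e.ks <= high]
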