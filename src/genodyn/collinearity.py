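"""Collinear and syntenic duplicated-segment discovery.

A WGD leaves duplicated blocks of genes whose order is conserved
(collinear) until rearrangement scrambles it; then only the co-occurrence
of paralogs in a neighborhood survives (synteny).  This module filters
homology hits by c-score (a hit's bit score relative to its query's best),
collapses tandem arrays, chains anchors into rank-monotone collinear
segments in the gene-order dot plot, clusters order-free syntenic
segments, and reports multiplicon ratios (two query segments covering one
reference segment is the 2:1 pattern diagnostic of a lineage-specific WGD).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

from .io_core import FeatureRecord, HitRecord, get_logger

__all__ = [
    "GeneOrder",
    "CollinearSegment",
    "MultipliconReport",
    "apply_c_score_filter",
    "collapse_tandem_arrays",
    "chain_anchors",
    "detect_syntenic_clusters",
    "find_duplication_ratio",
]

_LOG = get_logger("genodyn.collinear")


@dataclass
class GeneOrder:
    """Ordered gene lists per scaffold with a gene -> (scaffold, rank) index."""

    order: dict[str, list[tuple[str, str]]]  # scaffold -> [(gene_id, strand)]
    rank: dict[str, tuple[str, int]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.rank:
            for sid, genes in self.order.items():
                for pos, (gid, _strand) in enumerate(genes):
                    if gid in self.rank:
                        raise ValueError(f"gene {gid} appears more than once")
                    self.rank[gid] = (sid, pos)

    @classmethod
    def from_features(cls, features: Sequence[FeatureRecord]) -> "GeneOrder":
        """Rank genes by start coordinate per scaffold."""
        per_scaffold: dict[str, list[FeatureRecord]] = {}
        for rec in features:
            if rec.feature_class == "gene":
                per_scaffold.setdefault(rec.scaffold_id, []).append(rec)
        order = {
            sid: [(r.id, r.strand) for r in sorted(recs, key=lambda r: r.start)]
            for sid, recs in sorted(per_scaffold.items())
        }
        return cls(order=order)


@dataclass
class CollinearSegment:
    genome_a: str
    genome_b: str
    scaffold_a: str
    scaffold_b: str
    anchors: list[tuple[str, str]]
    orientation: str  # same | inverted
    mode: str         # collinear | syntenic

    @property
    def n_anchors(self) -> int:
        return len(self.anchors)


# ---------------------------------------------------------------------------
# Hit filtering
# ---------------------------------------------------------------------------

def apply_c_score_filter(
    hits: Sequence[HitRecord],
    c_score: float = 0.5,
    symmetric: bool = False,
) -> list[HitRecord]:
    """Drop weak homology hits relative to the best hit of the same query.

    A hit is kept iff bit_score >= c_score * best, where best is the top
    bit score among the query's hits (with ``symmetric=True``, the larger
    of the query's and the subject's best).  The boundary is kept.
    """
    best_q: dict[str, float] = {}
    best_s: dict[str, float] = {}
    for h in hits:
        best_q[h.query_id] = max(best_q.get(h.query_id, 0.0), h.bit_score)
        best_s[h.subject_id] = max(best_s.get(h.subject_id, 0.0), h.bit_score)
    kept = []
    for h in hits:
        ref = best_q[h.query_id]
        if symmetric:
            ref = max(ref, best_s[h.subject_id])
        if h.bit_score >= c_score * ref:
            kept.append(h)
    _LOG.info(
        "c-score filter (%.2f): %d hits in, %d kept, %d removed",
        c_score, len(hits), len(kept), len(hits) - len(kept),
    )
    return kept


def collapse_tandem_arrays(
    pairs: Sequence[tuple[str, str]],
    order: GeneOrder,
    window: int = 5,
) -> list[tuple[str, str]]:
    """Collapse tandem arrays to a single representative before chaining.

    Homologous genes on the same scaffold within ``window`` ranks are an
    array; each member maps to the array's lowest-rank gene, and pairs that
    become self-pairs are dropped.
    """
    parent: dict[str, str] = {}

    def find(g: str) -> str:
        parent.setdefault(g, g)
        while parent[g] != g:
            parent[g] = parent[parent[g]]
            g = parent[g]
        return g

    for a, b in pairs:
        if a not in order.rank or b not in order.rank:
            continue
        sa, ra = order.rank[a]
        sb, rb = order.rank[b]
        if sa == sb and abs(ra - rb) <= window and a != b:
            root_a, root_b = find(a), find(b)
            if root_a != root_b:
                # representative: the lower-rank gene
                keep, drop = sorted(
                    (root_a, root_b), key=lambda g: order.rank[g][1]
                )
                parent[drop] = keep

    collapsed: set[tuple[str, str]] = set()
    for a, b in pairs:
        ra, rb = find(a), find(b)
        if ra != rb:
            collapsed.add((ra, rb))
    return sorted(collapsed)


# ---------------------------------------------------------------------------
# Collinear chaining
# ---------------------------------------------------------------------------

def _anchor_points(
    order_a: GeneOrder,
    order_b: GeneOrder,
    pairs: Sequence[tuple[str, str]],
    same_genome: bool,
) -> dict[tuple[str, str], list[tuple[int, int, str, str]]]:
    """Anchor points (rank_a, rank_b, gene_a, gene_b) per scaffold pair."""
    buckets: dict[tuple[str, str], set[tuple[int, int, str, str]]] = {}
    for ga, gb in pairs:
        if ga not in order_a.rank or gb not in order_b.rank:
            continue
        if same_genome and ga == gb:
            continue  # a gene trivially matches itself
        sa, ra = order_a.rank[ga]
        sb, rb = order_b.rank[gb]
        if same_genome and (sa, ra) > (sb, rb):
            # canonical orientation avoids mirrored duplicate segments
            sa, ra, sb, rb, ga, gb = sb, rb, sa, ra, gb, ga
        buckets.setdefault((sa, sb), set()).add((ra, rb, ga, gb))
    return {key: sorted(pts) for key, pts in buckets.items()}


def chain_anchors(
    order_a: GeneOrder,
    order_b: GeneOrder,
    pairs: Sequence[tuple[str, str]],
    max_gap: int = 15,
    min_anchors: int = 5,
    genome_a: str = "A",
    genome_b: str = "B",
) -> list[CollinearSegment]:
    """Maximal rank-monotone anchor chains (collinear segments).

    A deterministic greedy sweep over anchors sorted by rank in genome A:
    an anchor extends the chain whose tail is strictly monotone with it
    (same or inverted orientation) within ``max_gap`` ranks in both
    genomes, ties going to the smaller tail rank in B; otherwise it opens a
    new chain.  Chains shorter than ``min_anchors`` are discarded.
    """
    same_genome = order_a is order_b or order_a.rank == order_b.rank
    segments: list[CollinearSegment] = []
    for (sa, sb), points in _anchor_points(order_a, order_b, pairs, same_genome).items():
        # chains: list of (orientation, [(ra, rb, ga, gb), ...])
        chains: list[tuple[str | None, list[tuple[int, int, str, str]]]] = []
        for ra, rb, ga, gb in points:
            candidates = []
            for ci, (orient, chain) in enumerate(chains):
                lra, lrb, _, _ = chain[-1]
                da, db = ra - lra, rb - lrb
                if not (0 < da <= max_gap):
                    continue
                if orient in (None, "same") and 0 < db <= max_gap:
                    candidates.append((lrb, ci, "same"))
                elif orient in (None, "inverted") and 0 < -db <= max_gap:
                    candidates.append((lrb, ci, "inverted"))
            if candidates:
                _lrb, ci, orient = min(candidates)
                chains[ci] = (orient, chains[ci][1] + [(ra, rb, ga, gb)])
            else:
                chains.append((None, [(ra, rb, ga, gb)]))
        for orient, chain in chains:
            if len(chain) < min_anchors:
                continue
            segments.append(
                CollinearSegment(
                    genome_a=genome_a, genome_b=genome_b,
                    scaffold_a=sa, scaffold_b=sb,
                    anchors=[(ga, gb) for _, _, ga, gb in chain],
                    orientation=orient or "same",
                    mode="collinear",
                )
            )
    _LOG.info("collinear chaining: %d segments (min_anchors=%d)",
              len(segments), min_anchors)
    return segments


# ---------------------------------------------------------------------------
# Order-free synteny
# ---------------------------------------------------------------------------

def detect_syntenic_clusters(
    order_a: GeneOrder,
    order_b: GeneOrder,
    pairs: Sequence[tuple[str, str]],
    window: int = 15,
    min_shared: int = 5,
    collinear_segments: Sequence[CollinearSegment] | None = None,
    genome_a: str = "A",
    genome_b: str = "B",
) -> list[CollinearSegment]:
    """Order-free syntenic segments: neighborhoods sharing enough homologs.

    Anchors within ``window`` ranks of each other in both genomes cluster
    together (transitively); clusters with >= ``min_shared`` anchors are
    segments.  Segments whose anchors are also chained by the collinear
    mode are labeled collinear, the remainder syntenic — so the syntenic
    detections always include the collinear ones.
    """
    if window < min_shared:
        raise ValueError(f"window {window} < min_shared {min_shared}")
    if collinear_segments is None:
        collinear_segments = chain_anchors(
            order_a, order_b, pairs, min_anchors=min_shared,
            genome_a=genome_a, genome_b=genome_b,
        )
    collinear_anchor_sets = [set(seg.anchors) for seg in collinear_segments]
    same_genome = order_a is order_b or order_a.rank == order_b.rank
    segments: list[CollinearSegment] = []
    for (sa, sb), points in _anchor_points(order_a, order_b, pairs, same_genome).items():
        n = len(points)
        parent = list(range(n))

        def find(i: int) -> int:
            while parent[i] != i:
                parent[i] = parent[parent[i]]
                i = parent[i]
            return i

        for i in range(n):
            for j in range(i + 1, n):
                if points[j][0] - points[i][0] > window:
                    break  # points sorted by rank_a
                if abs(points[j][1] - points[i][1]) <= window:
                    pi, pj = find(i), find(j)
                    if pi != pj:
                        parent[pj] = pi
        clusters: dict[int, list[int]] = {}
        for i in range(n):
            clusters.setdefault(find(i), []).append(i)
        for members in clusters.values():
            if len(members) < min_shared:
                continue
            anchors = [(points[i][2], points[i][3]) for i in sorted(members)]
            anchor_set = set(anchors)
            is_collinear = any(
                cset and cset <= anchor_set for cset in collinear_anchor_sets
            )
            segments.append(
                CollinearSegment(
                    genome_a=genome_a, genome_b=genome_b,
                    scaffold_a=sa, scaffold_b=sb,
                    anchors=anchors,
                    orientation="same",
                    mode="collinear" if is_collinear else "syntenic",
                )
            )
    _LOG.info("syntenic clustering: %d segments", len(segments))
    return segments


# ---------------------------------------------------------------------------
# Multiplicon ratios
# ---------------------------------------------------------------------------

@dataclass
class MultipliconReport:
    ref_scaffold: str
    ref_start: int     # rank of first reference anchor
    ref_end: int       # rank of last reference anchor (inclusive)
    ratio: int
    query_scaffolds: list[str]


def _rank_interval(seg: CollinearSegment, order: GeneOrder, side: str) -> tuple[str, int, int]:
    genes = [a if side == "a" else b for a, b in seg.anchors]
    ranks = [order.rank[g][1] for g in genes]
    sid = seg.scaffold_a if side == "a" else seg.scaffold_b
    return sid, min(ranks), max(ranks)


def find_duplication_ratio(
    segments: Sequence[CollinearSegment],
    order_ref: GeneOrder,
    order_query: GeneOrder,
) -> list[MultipliconReport]:
    """Multiplicon ratios of reference regions against a query genome.

    Reference-side segment intervals that overlap are merged into regions;
    a region's ratio is the number of pairwise-disjoint query-side
    intervals covering it.  Ratio 2 is the one-reference-to-two-query
    pattern expected when the query lineage (and not the reference)
    underwent a WGD.
    """
    entries = []
    for seg in segments:
        ref_iv = _rank_interval(seg, order_ref, "a")
        q_iv = _rank_interval(seg, order_query, "b")
        entries.append((ref_iv, q_iv))

    # merge overlapping reference intervals per scaffold into regions
    by_scaffold: dict[str, list[tuple[tuple[int, int], tuple[str, int, int]]]] = {}
    for (rsid, rs, re_), q_iv in entries:
        by_scaffold.setdefault(rsid, []).append(((rs, re_), q_iv))
    reports: list[MultipliconReport] = []
    for rsid, items in sorted(by_scaffold.items()):
        items.sort(key=lambda t: t[0])
        region: list[tuple[tuple[int, int], tuple[str, int, int]]] = []

        def flush(region_items) -> None:
            if not region_items:
                return
            rs = min(iv[0] for iv, _ in region_items)
            re_ = max(iv[1] for iv, _ in region_items)
            # count pairwise-disjoint query intervals (greedy by end rank)
            chosen: list[tuple[str, int, int]] = []
            for q in sorted({q for _, q in region_items}, key=lambda q: (q[0], q[2])):
                if all(
                    q[0] != c[0] or q[1] > c[2] or q[2] < c[1] for c in chosen
                ):
                    chosen.append(q)
            reports.append(
                MultipliconReport(
                    ref_scaffold=rsid, ref_start=rs, ref_end=re_,
                    ratio=len(chosen),
                    query_scaffolds=sorted({c[0] for c in chosen}),
                )
            )

        for iv, q_iv in items:
            if region and iv[0] <= max(r[0][1] for r in region):
                region.append((iv, q_iv))
            else:
                flush(region)
                region = [(iv, q_iv)]
        flush(region)
    return reports
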