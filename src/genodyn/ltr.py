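"""LTR-retrotransposon lifecycle analysis.

Classifies elements into superfamilies from their ordered protein-domain
architecture, separates intact / truncated / solo / non-autonomous copies
with the four solo-LTR decoy filters (truncated overlap, scaffold edge,
coverage/identity, assembly gap), and dates insertions from the divergence
of an element's two LTRs under a molecular clock: at insertion the 5' and
3' LTR are identical, so their Kimura two-parameter distance K gives the
age T = K / (2 r) for a substitution rate r per site per year.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
from numba import njit

from .io_core import GapRegistry, HitRecord, SaturationError, get_logger

__all__ = [
    "DomainHit",
    "LtrElement",
    "InsertionEstimate",
    "classify_by_domains",
    "check_intact",
    "extract_rt_candidates",
    "align_pair_global",
    "k2p_distance",
    "date_insertion",
    "date_element",
    "date_elements",
    "ltr_pairs_from_features",
    "detect_truncated_loci",
    "detect_solo_ltrs",
    "solo_intact_ratio",
    "insertion_age_profile",
    "INTACT_DOMAINS",
]

_LOG = get_logger("genodyn.ltr")

#: Domains an element must retain to count as intact.
INTACT_DOMAINS = frozenset({"GAG", "AP", "INT", "RT", "RH"})

_DOMAIN_VOCAB = {"GAG", "AP", "INT", "RT", "RH", "ENV"}
_DOMAIN_ALIASES = {"RNASEH": "RH", "RNaseH": "RH"}


def _canon_domain(token: str) -> str:
    token = _DOMAIN_ALIASES.get(token, _DOMAIN_ALIASES.get(token.upper(), token))
    if token not in _DOMAIN_VOCAB:
        raise ValueError(f"unknown domain token {token!r}")
    return token


@dataclass
class DomainHit:
    """A protein-domain alignment on an element (element-local coordinates)."""

    element_id: str
    domain: str
    start: int
    end: int
    score: float = 0.0

    def __post_init__(self) -> None:
        self.domain = _canon_domain(self.domain)
        if not self.start < self.end:
            raise ValueError(f"domain hit {self.element_id}: start >= end")


@dataclass
class LtrElement:
    id: str
    scaffold_id: str
    five_ltr: tuple[int, int] | None = None
    internal: tuple[int, int] | None = None
    three_ltr: tuple[int, int] | None = None
    status: str = "unclassified"
    superfamily: str = "non_autonomous"

    @property
    def span(self) -> tuple[int, int]:
        coords = [c for iv in (self.five_ltr, self.internal, self.three_ltr)
                  if iv is not None for c in iv]
        return (min(coords), max(coords))


@dataclass
class InsertionEstimate:
    """Dating record for one element: K2P components and T = K/(2r)."""

    element_id: str
    P: float
    Q: float
    K: float
    r: float
    T: float
    superfamily: str = ""


# ---------------------------------------------------------------------------
# Domain-architecture classification
# ---------------------------------------------------------------------------

_CORE = {"INT", "RT", "RH"}
_COPIA_ORDERS = (("INT", "RT", "RH"), ("RH", "RT", "INT"))
_GYPSY_ORDERS = (("RT", "RH", "INT"), ("INT", "RH", "RT"))


def classify_by_domains(ordered_domains: list[str]) -> str:
    """Superfamily from the element-local order of coding domains.

    ENV anywhere marks Retroviridae.  Otherwise the order of the core
    INT/RT/RH triplet decides Ty1-copia vs Ty3-gypsy; a partial core is
    'incomplete' and an empty domain list is 'non_autonomous'.
    """
    domains = [_canon_domain(d) for d in ordered_domains]
    if "ENV" in domains:
        return "Retroviridae"
    core = tuple(d for d in domains if d in _CORE)
    if core in _COPIA_ORDERS:
        return "Ty1_copia"
    if core in _GYPSY_ORDERS:
        return "Ty3_gypsy"
    if core:
        return "incomplete"
    return "non_autonomous"


def check_intact(domain_set) -> bool:
    """True iff the element retains all of GAG, AP, INT, RT and RH."""
    return INTACT_DOMAINS <= {_canon_domain(d) for d in domain_set}


def extract_rt_candidates(segments: list[str]) -> str | None:
    """Pick at most one reverse-transcriptase amino-acid segment per element.

    Segments of 140 aa or fewer, or with two or more stop codons ('*'),
    are discarded; the longest survivor wins (first on ties).
    """
    best: str | None = None
    best_len = -1
    for seg in segments:
        aa_len = len(seg) - seg.count("*")
        if aa_len <= 140 or seg.count("*") >= 2:
            continue
        if aa_len > best_len:
            best, best_len = seg, aa_len
    return best


# ---------------------------------------------------------------------------
# Affine-gap global pairwise alignment (Gotoh)
# ---------------------------------------------------------------------------

# traceback states
_M, _IX, _IY = 0, 1, 2
_NEG = -(10 ** 9)


@njit(cache=False)
def _gotoh_fill(a, b, match, mismatch, gap_open, gap_extend):  # pragma: no cover
    m, n = a.shape[0], b.shape[0]
    prev_m = np.full(n + 1, _NEG, dtype=np.int64)
    prev_x = np.full(n + 1, _NEG, dtype=np.int64)
    prev_y = np.full(n + 1, _NEG, dtype=np.int64)
    tb_m = np.zeros((m + 1, n + 1), dtype=np.int8)
    tb_x = np.zeros((m + 1, n + 1), dtype=np.int8)
    tb_y = np.zeros((m + 1, n + 1), dtype=np.int8)
    prev_m[0] = 0
    for j in range(1, n + 1):
        prev_y[j] = gap_open + j * gap_extend
        tb_y[0, j] = _IY if j > 1 else _M
    cur_m = np.empty(n + 1, dtype=np.int64)
    cur_x = np.empty(n + 1, dtype=np.int64)
    cur_y = np.empty(n + 1, dtype=np.int64)
    for i in range(1, m + 1):
        cur_m[0] = _NEG
        cur_y[0] = _NEG
        cur_x[0] = gap_open + i * gap_extend
        tb_x[i, 0] = _IX if i > 1 else _M
        for j in range(1, n + 1):
            # match state: diagonal from best of three, prefer M then IX then IY
            s = match if a[i - 1] == b[j - 1] else mismatch
            best = prev_m[j - 1]
            state = _M
            if prev_x[j - 1] > best:
                best, state = prev_x[j - 1], _IX
            if prev_y[j - 1] > best:
                best, state = prev_y[j - 1], _IY
            cur_m[j] = best + s
            tb_m[i, j] = state
            # IX: gap in b, consume a[i-1] ("up")
            open_x = prev_m[j] + gap_open + gap_extend
            ext_x = prev_x[j] + gap_extend
            switch_x = prev_y[j] + gap_open + gap_extend
            best, state = open_x, _M
            if ext_x > best:
                best, state = ext_x, _IX
            if switch_x > best:
                best, state = switch_x, _IY
            cur_x[j] = best
            tb_x[i, j] = state
            # IY: gap in a, consume b[j-1] ("left")
            open_y = cur_m[j - 1] + gap_open + gap_extend
            ext_y = cur_y[j - 1] + gap_extend
            switch_y = cur_x[j - 1] + gap_open + gap_extend
            best, state = open_y, _M
            if ext_y > best:
                best, state = ext_y, _IY
            if switch_y > best:
                best, state = switch_y, _IX
            cur_y[j] = best
            tb_y[i, j] = state
        prev_m, cur_m = cur_m, prev_m
        prev_x, cur_x = cur_x, prev_x
        prev_y, cur_y = cur_y, prev_y
    return prev_m[n], prev_x[n], prev_y[n], tb_m, tb_x, tb_y


def align_pair_global(
    seq_a: str,
    seq_b: str,
    match: int = 5,
    mismatch: int = -4,
    gap_open: int = -10,
    gap_extend: int = -1,
) -> tuple[str, str, int]:
    """Optimal-score affine-gap global alignment of two nucleotide sequences.

    Returns the two gapped sequences and the alignment score.  Ties are
    broken deterministically: diagonal (match state) preferred, then up
    (gap in ``seq_b``), then left.
    """
    if not seq_a or not seq_b:
        raise ValueError("cannot align an empty sequence")
    a = np.frombuffer(seq_a.encode("ascii"), dtype=np.uint8)
    b = np.frombuffer(seq_b.encode("ascii"), dtype=np.uint8)
    sm, sx, sy, tb_m, tb_x, tb_y = _gotoh_fill(
        a, b, match, mismatch, gap_open, gap_extend
    )
    # end-state selection with the same preference order
    score, state = sm, _M
    if sx > score:
        score, state = sx, _IX
    if sy > score:
        score, state = sy, _IY
    i, j = len(seq_a), len(seq_b)
    out_a: list[str] = []
    out_b: list[str] = []
    while i > 0 or j > 0:
        if state == _M:
            prev = tb_m[i, j]
            out_a.append(seq_a[i - 1])
            out_b.append(seq_b[j - 1])
            i, j = i - 1, j - 1
        elif state == _IX:
            prev = tb_x[i, j]
            out_a.append(seq_a[i - 1])
            out_b.append("-")
            i -= 1
        else:
            prev = tb_y[i, j]
            out_a.append("-")
            out_b.append(seq_b[j - 1])
            j -= 1
        state = prev
    return "".join(reversed(out_a)), "".join(reversed(out_b)), int(score)


# ---------------------------------------------------------------------------
# Kimura two-parameter distance and dating
# ---------------------------------------------------------------------------

_PURINES = {"A", "G"}
_PYRIMIDINES = {"C", "T"}


def k2p_distance(aligned_a: str, aligned_b: str) -> tuple[float, float, float]:
    """Kimura two-parameter distance from a pairwise alignment.

    P and Q are the transition and transversion proportions over ungapped,
    unambiguous columns; K = -1/2 * ln((1 - 2P - Q) * sqrt(1 - 2Q)).
    Saturated alignments (non-positive log argument) raise
    :class:`SaturationError` so callers can flag the element undatable.
    """
    if len(aligned_a) != len(aligned_b):
        raise ValueError("aligned sequences differ in length")
    usable = transitions = transversions = 0
    for x, y in zip(aligned_a, aligned_b):
        if x in "-N" or y in "-N":
            continue
        usable += 1
        if x == y:
            continue
        if (x in _PURINES and y in _PURINES) or (
            x in _PYRIMIDINES and y in _PYRIMIDINES
        ):
            transitions += 1
        else:
            transversions += 1
    if usable == 0:
        raise ValueError("no ungapped, unambiguous columns in alignment")
    P = transitions / usable
    Q = transversions / usable
    w1 = 1.0 - 2.0 * P - Q
    w2 = 1.0 - 2.0 * Q
    if w1 <= 0.0 or w2 <= 0.0:
        raise SaturationError(
            f"K2P saturated (P={P:.4f}, Q={Q:.4f}); element undatable"
        )
    K = -0.5 * math.log(w1 * math.sqrt(w2))
    return P, Q, K


def date_insertion(K: float, r: float) -> float:
    """Insertion age in years: T = K / (2 r)."""
    if r <= 0:
        raise ValueError(f"substitution rate must be positive, got {r}")
    if K < 0:
        raise ValueError(f"distance must be non-negative, got {K}")
    return K / (2.0 * r)


def date_element(
    ltr5: str,
    ltr3: str,
    element_id: str,
    r: float,
    superfamily: str = "",
    **align_kwargs,
) -> InsertionEstimate:
    """Full dating pipeline for one element: align the two LTRs, compute the
    K2P distance, and convert to years."""
    a, b, _score = align_pair_global(ltr5, ltr3, **align_kwargs)
    P, Q, K = k2p_distance(a, b)
    T = date_insertion(K, r)
    return InsertionEstimate(element_id, P, Q, K, r, T, superfamily)


def ltr_pairs_from_features(genome, features) -> dict[str, tuple[str, str]]:
    """Extract (5' LTR, 3' LTR) sequences per element from LTR_terminus
    annotations (attributes ``element`` and ``side``)."""
    pairs: dict[str, dict[str, str]] = {}
    for rec in features:
        if rec.feature_class != "LTR_terminus":
            continue
        eid = rec.attributes.get("element", rec.id.rsplit("_", 1)[0])
        side = rec.attributes.get("side", "5" if rec.id.endswith("5LTR") else "3")
        seq = genome.scaffolds[rec.scaffold_id][rec.start:rec.end]
        pairs.setdefault(eid, {})[side] = seq
    return {
        eid: (sides["5"], sides["3"])
        for eid, sides in pairs.items()
        if "5" in sides and "3" in sides
    }


def date_elements(
    ltr_pairs: dict[str, tuple[str, str]],
    r: float,
    superfamilies: dict[str, str] | None = None,
    **align_kwargs,
) -> tuple[list[InsertionEstimate], list[str]]:
    """Date every element with a complete LTR pair; returns the estimates
    and the ids of elements whose alignment hit K2P saturation."""
    superfamilies = superfamilies or {}
    estimates: list[InsertionEstimate] = []
    undatable: list[str] = []
    for eid in sorted(ltr_pairs):
        ltr5, ltr3 = ltr_pairs[eid]
        try:
            estimates.append(
                date_element(ltr5, ltr3, eid, r,
                             superfamilies.get(eid, ""), **align_kwargs)
            )
        except SaturationError:
            undatable.append(eid)
    _LOG.info("dating: %d elements dated, %d undatable (saturated)",
              len(estimates), len(undatable))
    return estimates, undatable


# ---------------------------------------------------------------------------
# Truncated and solo-LTR detection
# ---------------------------------------------------------------------------

def _merge_intervals(ivs: list[tuple[int, int]]) -> list[tuple[int, int]]:
    out: list[tuple[int, int]] = []
    for s, e in sorted(ivs):
        if out and s <= out[-1][1]:
            out[-1] = (out[-1][0], max(out[-1][1], e))
        else:
            out.append((s, e))
    return out


def _overlaps(s1: int, e1: int, s2: int, e2: int) -> bool:
    return s1 < e2 and s2 < e1


def detect_truncated_loci(
    hits: list[HitRecord],
    query_lengths: dict[str, int],
    intact_intervals: dict[str, list[tuple[int, int]]] | None = None,
    min_coverage: float = 0.8,
    min_identity: float = 0.6,
) -> dict[str, list[tuple[int, int]]]:
    """Genomic loci carrying truncated element copies.

    A full-element-vs-genome hit qualifies when coverage (aligned query
    length / query length) is strictly above ``min_coverage`` and identity
    strictly above ``min_identity``; hits that coincide with annotated
    intact elements are self-matches and skipped.  Overlapping qualifying
    hits merge into one locus per scaffold.
    """
    intact_intervals = intact_intervals or {}
    per_scaffold: dict[str, list[tuple[int, int]]] = {}
    for hit in hits:
        if hit.query_id not in query_lengths:
            raise ValueError(f"missing query length for {hit.query_id}")
        coverage = hit.aln_length / query_lengths[hit.query_id]
        identity = hit.pct_identity / 100.0
        if not (coverage > min_coverage and identity > min_identity):
            continue
        s, e = hit.subject_interval()
        if any(
            _overlaps(s, e, i_s, i_e)
            for i_s, i_e in intact_intervals.get(hit.subject_id, [])
        ):
            continue
        per_scaffold.setdefault(hit.subject_id, []).append((s, e))
    return {sid: _merge_intervals(ivs) for sid, ivs in per_scaffold.items()}


@dataclass
class SoloDetection:
    loci: list[tuple[str, int, int, str]]  # scaffold, start, end, best query
    rejections: dict[str, int] = field(default_factory=dict)


def detect_solo_ltrs(
    hits: list[HitRecord],
    query_lengths: dict[str, int],
    truncated_loci: dict[str, list[tuple[int, int]]],
    gaps: GapRegistry,
    scaffold_lengths: dict[str, int],
    intact_intervals: dict[str, list[tuple[int, int]]] | None = None,
    min_coverage: float = 0.7,
    min_identity: float = 0.7,
    edge_distance: int = 5000,
    gap_distance: int = 500,
) -> SoloDetection:
    """Solo-LTR loci from LTR-terminus-vs-genome hits, with the four decoy
    filters and per-filter rejection counts.

    Candidates are hits away from annotated intact elements.  A candidate is
    rejected by the first failing rule: (a) overlap with a truncated locus;
    (b) strictly less than ``edge_distance`` bases from a scaffold end;
    (c) coverage < ``min_coverage`` or identity < ``min_identity``;
    (d) strictly less than ``gap_distance`` bases from an assembly gap.
    Survivors are deduplicated to non-overlapping loci keeping the highest
    bit score.
    """
    intact_intervals = intact_intervals or {}
    rejections = {"a_truncated_overlap": 0, "b_scaffold_edge": 0,
                  "c_coverage_identity": 0, "d_gap_adjacent": 0}
    survivors: list[tuple[float, str, int, int, str]] = []
    n_candidates = 0
    for hit in hits:
        if hit.query_id not in query_lengths:
            raise ValueError(f"missing query length for {hit.query_id}")
        s, e = hit.subject_interval()
        sid = hit.subject_id
        if any(
            _overlaps(s, e, i_s, i_e)
            for i_s, i_e in intact_intervals.get(sid, [])
        ):
            continue  # the element's own LTR, not a candidate
        n_candidates += 1
        if any(_overlaps(s, e, t_s, t_e) for t_s, t_e in truncated_loci.get(sid, [])):
            rejections["a_truncated_overlap"] += 1
            continue
        slen = scaffold_lengths[sid]
        if s < edge_distance or (slen - e) < edge_distance:
            rejections["b_scaffold_edge"] += 1
            continue
        coverage = hit.aln_length / query_lengths[hit.query_id]
        identity = hit.pct_identity / 100.0
        if coverage < min_coverage or identity < min_identity:
            rejections["c_coverage_identity"] += 1
            continue
        near_gap = any(
            max(g_s - e, s - g_e, 0) < gap_distance
            for g_s, g_e in gaps.for_scaffold(sid)
        )
        if near_gap:
            rejections["d_gap_adjacent"] += 1
            continue
        survivors.append((hit.bit_score, sid, s, e, hit.query_id))

    # deduplicate to non-overlapping loci, best bit score first
    survivors.sort(key=lambda t: -t[0])
    kept: list[tuple[str, int, int, str]] = []
    for _score, sid, s, e, qid in survivors:
        if any(o_sid == sid and _overlaps(s, e, o_s, o_e) for o_sid, o_s, o_e, _ in kept):
            continue
        kept.append((sid, s, e, qid))
    kept.sort()
    _LOG.info(
        "solo-LTR detection: %d candidates, rejections %s, %d loci kept",
        n_candidates, rejections, len(kept),
    )
    return SoloDetection(loci=kept, rejections=rejections)


def solo_intact_ratio(n_solo: int, n_intact: int) -> float | None:
    """Solo:intact copy ratio, rounded to two decimals (half away from zero).

    Undefined (None) when there are no intact elements.
    """
    if n_intact == 0:
        return None
    ratio = Decimal(n_solo) / Decimal(n_intact)
    return float(ratio.quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


# ---------------------------------------------------------------------------
# Age profiles
# ---------------------------------------------------------------------------

@dataclass
class AgeProfile:
    bin_edges: np.ndarray       # years
    counts: np.ndarray
    mode: float                 # center of the max-count bin, years
    by_superfamily: dict[str, np.ndarray] = field(default_factory=dict)


def insertion_age_profile(
    estimates: list[InsertionEstimate],
    bin_width: float,
) -> AgeProfile:
    """Histogram of insertion ages with the modal bin center; counts are also
    stratified by superfamily when the estimates carry one."""
    if not estimates:
        raise ValueError("no dated elements")
    ages = np.array([est.T for est in estimates], dtype=float)
    n_bins = int(np.ceil((ages.max() + 1e-9) / bin_width)) or 1
    edges = np.arange(n_bins + 1) * bin_width
    counts, _ = np.histogram(ages, bins=edges)
    mode_idx = int(np.argmax(counts))
    mode = (edges[mode_idx] + edges[mode_idx + 1]) / 2.0
    by_sf: dict[str, np.ndarray] = {}
    for sf in sorted({e.superfamily for e in estimates if e.superfamily}):
        sub = np.array([e.T for e in estimates if e.superfamily == sf])
        by_sf[sf], _ = np.histogram(sub, bins=edges)
    return AgeProfile(bin_edges=edges, counts=counts, mode=mode, by_superfamily=by_sf)
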