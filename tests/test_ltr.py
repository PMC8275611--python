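"""Domain classification, alignment, K2P dating, and the solo-LTR filters."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import genodyn as g
from genodyn.io_core import GapRegistry, HitRecord, SaturationError
from genodyn.ltr import SoloDetection


# ---------------------------------------------------------------------------
# Domain architecture
# ---------------------------------------------------------------------------

@pytest.mark.parametrize(
    "domains,expected",
    [
        (["INT", "RT", "RH"], "Ty1_copia"),
        (["RH", "RT", "INT"], "Ty1_copia"),
        (["RT", "RH", "INT"], "Ty3_gypsy"),
        (["INT", "RH", "RT"], "Ty3_gypsy"),
        (["GAG", "ENV", "RT"], "Retroviridae"),
        (["INT", "RT"], "incomplete"),
        (["RT"], "incomplete"),
        ([], "non_autonomous"),
        (["GAG", "AP"], "non_autonomous"),  # no core domains at all
        (["GAG", "AP", "INT", "RT", "RNaseH"], "Ty1_copia"),  # alias accepted
    ],
)
def test_classify_by_domains(domains, expected):
    assert g.classify_by_domains(domains) == expected


def test_classify_rejects_unknown_domain():
    with pytest.raises(ValueError, match="unknown domain"):
        g.classify_by_domains(["FOO"])


@settings(deadline=None, max_examples=200, derandomize=True)
@given(st.lists(st.sampled_from(["GAG", "AP", "INT", "RT", "RH", "ENV"]),
                max_size=8))
def test_classification_is_total(domains):
    """Every domain arrangement maps to exactly one of the five classes."""
    assert g.classify_by_domains(domains) in {
        "Ty1_copia", "Ty3_gypsy", "Retroviridae", "incomplete", "non_autonomous",
    }


@pytest.mark.parametrize(
    "domain_set,expected",
    [
        ({"GAG", "AP", "INT", "RT", "RH"}, True),
        ({"GAG", "INT", "RT", "RH"}, False),
        (set(), False),
        ({"GAG", "AP", "INT", "RT", "RH", "ENV"}, True),
    ],
)
def test_check_intact(domain_set, expected):
    assert g.check_intact(domain_set) is expected


@pytest.mark.parametrize(
    "segments,expected",
    [
        (["M" * 150], "M" * 150),
        (["M" * 120], None),
        (["M" * 150 + "*", "M" * 200 + "*"], "M" * 200 + "*"),  # 1 stop each
        (["M" * 300 + "**"], None),                             # 2 stops
        ([], None),
    ],
)
def test_extract_rt_candidates(segments, expected):
    assert g.extract_rt_candidates(segments) == expected


def test_extract_rt_boundary_is_strict():
    # exactly 140 aa is not enough
    assert g.extract_rt_candidates(["M" * 140]) is None
    assert g.extract_rt_candidates(["M" * 141]) == "M" * 141


# ---------------------------------------------------------------------------
# Alignment: brute-force oracle
# ---------------------------------------------------------------------------

def _oracle_score(a, b, match=5, mismatch=-4, go=-10, ge=-1):
    """Exhaustive three-state affine-gap DP (same recurrence, plain Python)."""
    NEG = float("-inf")
    m, n = len(a), len(b)
    M = [[NEG] * (n + 1) for _ in range(m + 1)]
    X = [[NEG] * (n + 1) for _ in range(m + 1)]
    Y = [[NEG] * (n + 1) for _ in range(m + 1)]
    M[0][0] = 0
    for i in range(1, m + 1):
        X[i][0] = go + i * ge
    for j in range(1, n + 1):
        Y[0][j] = go + j * ge
    for i in range(1, m + 1):
        for j in range(1, n + 1):
            s = match if a[i - 1] == b[j - 1] else mismatch
            M[i][j] = max(M[i - 1][j - 1], X[i - 1][j - 1], Y[i - 1][j - 1]) + s
            X[i][j] = max(M[i - 1][j] + go + ge, X[i - 1][j] + ge,
                          Y[i - 1][j] + go + ge)
            Y[i][j] = max(M[i][j - 1] + go + ge, Y[i][j - 1] + ge,
                          X[i][j - 1] + go + ge)
    return max(M[m][n], X[m][n], Y[m][n])


def _score_alignment(aligned_a, aligned_b, match=5, mismatch=-4, go=-10, ge=-1):
    score, gap_a, gap_b = 0, False, False
    for x, y in zip(aligned_a, aligned_b):
        if x == "-":
            score += ge if gap_a else go + ge
            gap_a, gap_b = True, False
        elif y == "-":
            score += ge if gap_b else go + ge
            gap_b, gap_a = True, False
        else:
            score += match if x == y else mismatch
            gap_a = gap_b = False
    return score


def test_align_identical():
    a, b, score = g.align_pair_global("ACGT", "ACGT")
    assert a == b == "ACGT" and score == 20


def test_align_single_gap():
    a, b, score = g.align_pair_global("ACGT", "AGT")
    assert (a, b) == ("ACGT", "A-GT")
    assert score == 3 * 5 - 11


def test_align_prefers_mismatches_over_gaps_at_these_scores():
    a, b, score = g.align_pair_global("AAAA", "TTTT")
    assert (a, b) == ("AAAA", "TTTT") and score == -16


def test_align_empty_input_errors():
    with pytest.raises(ValueError):
        g.align_pair_global("", "ACGT")


@settings(deadline=None, max_examples=60, derandomize=True)
@given(
    a=st.text(alphabet="ACGT", min_size=1, max_size=9),
    b=st.text(alphabet="ACGT", min_size=1, max_size=9),
)
def test_align_matches_bruteforce_oracle(a, b):
    """Optimal score agrees with an exhaustive DP, and the returned alignment
    is consistent (strips to the inputs, re-scores to the reported score)."""
    aa, bb, score = g.align_pair_global(a, b)
    assert score == _oracle_score(a, b)
    assert aa.replace("-", "") == a and bb.replace("-", "") == b
    assert _score_alignment(aa, bb) == score


# ---------------------------------------------------------------------------
# K2P distance and dating
# ---------------------------------------------------------------------------

def test_k2p_identical_is_zero():
    assert g.k2p_distance("ACGTT", "ACGTT") == (0.0, 0.0, 0.0)


def test_k2p_closed_form():
    # 100 columns: 10 transitions (A<->G), 5 transversions (A<->C)
    a = "A" * 100
    b = "G" * 10 + "C" * 5 + "A" * 85
    P, Q, K = g.k2p_distance(a, b)
    assert (P, Q) == (0.10, 0.05)
    expected = -0.5 * math.log((1 - 2 * 0.1 - 0.05) * math.sqrt(1 - 2 * 0.05))
    assert K == pytest.approx(expected)
    assert K == pytest.approx(0.1702, abs=5e-4)


def test_k2p_saturation_error():
    a = "A" * 100
    b = "G" * 50 + "A" * 50  # P = 0.5, Q = 0
    with pytest.raises(SaturationError):
        g.k2p_distance(a, b)


def test_k2p_skips_gap_and_n_columns():
    P, Q, K = g.k2p_distance("ACG-N", "ACGTG")
    assert (P, Q, K) == (0.0, 0.0, 0.0)


@settings(deadline=None, max_examples=100, derandomize=True)
@given(
    n_ts=st.integers(min_value=0, max_value=20),
    n_tv=st.integers(min_value=0, max_value=15),
)
def test_k2p_correction_never_shrinks_raw_distance(n_ts, n_tv):
    a = "A" * 100
    b = "G" * n_ts + "C" * n_tv + "A" * (100 - n_ts - n_tv)
    try:
        P, Q, K = g.k2p_distance(a, b)
    except SaturationError:
        return
    assert K >= P + Q - 1e-12


@pytest.mark.parametrize(
    "K,r,expected",
    [
        (0.0, 2.2e-9, 0.0),
        (0.0044, 2.2e-9, 1.0e6),
        (0.036, 1.8e-8, 1.0e6),
    ],
)
def test_date_insertion(K, r, expected):
    assert g.date_insertion(K, r) == pytest.approx(expected)


def test_date_insertion_rejects_bad_rate():
    with pytest.raises(ValueError):
        g.date_insertion(0.1, 0.0)


# ---------------------------------------------------------------------------
# Solo:intact ratio (printed-count arithmetic lives in test_acceptance too)
# ---------------------------------------------------------------------------

def test_solo_intact_ratio_rounding_half_away_from_zero():
    assert g.solo_intact_ratio(5, 2) == 2.5
    assert g.solo_intact_ratio(1, 8) == 0.13  # 0.125 rounds up
    assert g.solo_intact_ratio(0, 7) == 0.0


def test_solo_intact_ratio_undefined_without_intact():
    assert g.solo_intact_ratio(10, 0) is None


# ---------------------------------------------------------------------------
# Truncated and solo detection rules
# ---------------------------------------------------------------------------

def _mk_hit(qid, sid, identity, aln_len, s_start, s_end, bit=100.0):
    return HitRecord(qid, sid, identity, aln_len, 0, 0, 1, aln_len,
                     s_start, s_end, 1e-40, bit)


@pytest.mark.parametrize(
    "coverage,identity,expected",
    [
        (0.85, 65.0, 1),   # both above -> truncated locus
        (0.85, 55.0, 0),   # identity bound
        (0.50, 90.0, 0),   # coverage bound
        (0.80, 65.0, 0),   # boundary is strict
    ],
)
def test_detect_truncated_thresholds(coverage, identity, expected):
    hit = _mk_hit("el1", "s1", identity, int(coverage * 1000), 5001, 5000 + int(coverage * 1000))
    loci = g.detect_truncated_loci([hit], {"el1": 1000})
    assert sum(len(v) for v in loci.values()) == expected


def test_detect_truncated_requires_query_length():
    with pytest.raises(ValueError, match="missing query length"):
        g.detect_truncated_loci([_mk_hit("el1", "s1", 90.0, 900, 1, 900)], {})


def _run_solo(hits, truncated=None, gaps=None, scaffold_len=100_000):
    return g.detect_solo_ltrs(
        hits, {"q": 1000},
        truncated or {},
        gaps or GapRegistry([], 1),
        {"s1": scaffold_len},
    )


def test_solo_filter_b_scaffold_edge():
    det = _run_solo([_mk_hit("q", "s1", 95.0, 1000, 3001, 4000)])
    assert det.loci == [] and det.rejections["b_scaffold_edge"] == 1


def test_solo_filter_c_coverage_identity():
    det = _run_solo([_mk_hit("q", "s1", 90.0, 650, 50_001, 50_650)])
    assert det.loci == [] and det.rejections["c_coverage_identity"] == 1


def test_solo_filter_d_gap_adjacent():
    gaps = GapRegistry([("s1", 52_000, 52_200)], 10)
    det = _run_solo([_mk_hit("q", "s1", 95.0, 1000, 50_601, 51_600)], gaps=gaps)
    assert det.loci == [] and det.rejections["d_gap_adjacent"] == 1


def test_solo_filter_a_truncated_overlap():
    truncated = {"s1": [(50_500, 51_500)]}
    det = _run_solo([_mk_hit("q", "s1", 95.0, 1000, 50_001, 51_000)],
                    truncated=truncated)
    assert det.loci == [] and det.rejections["a_truncated_overlap"] == 1


def test_solo_survivor_passes_all_filters():
    det = _run_solo([_mk_hit("q", "s1", 85.0, 900, 50_001, 50_900)])
    assert det.loci == [("s1", 50_000, 50_900, "q")]
    assert sum(det.rejections.values()) == 0


def test_solo_gap_distance_boundary_is_strict():
    # locus end 50_900, gap starts at 51_400: distance exactly 500 -> kept
    gaps = GapRegistry([("s1", 51_400, 51_600)], 10)
    det = _run_solo([_mk_hit("q", "s1", 95.0, 900, 50_001, 50_900)], gaps=gaps)
    assert len(det.loci) == 1


def test_solo_dedup_keeps_best_bit_score():
    hits = [
        _mk_hit("q", "s1", 95.0, 900, 50_001, 50_900, bit=100.0),
        _mk_hit("q", "s1", 90.0, 900, 50_301, 51_200, bit=80.0),
    ]
    det = _run_solo(hits)
    assert det.loci == [("s1", 50_000, 50_900, "q")]


# ---------------------------------------------------------------------------
# Age profiles
# ---------------------------------------------------------------------------

def _est(t):
    return g.InsertionEstimate("e", 0, 0, 2 * 2.2e-9 * t, 2.2e-9, t)


def test_age_profile_single_bin_mode():
    profile = g.insertion_age_profile([_est(1.0e6)] * 5, bin_width=0.5e6)
    assert profile.counts.sum() == 5
    lo = profile.bin_edges[np.argmax(profile.counts)]
    assert lo <= 1.0e6 <= lo + 0.5e6
    assert lo <= profile.mode <= lo + 0.5e6


def test_age_profile_uniform_is_flat():
    rng = np.random.default_rng(1)
    ages = rng.uniform(0, 4e6, 4000)
    profile = g.insertion_age_profile([_est(t) for t in ages], bin_width=0.5e6)
    from scipy import stats
    chi2 = stats.chisquare(profile.counts).pvalue
    assert chi2 > 0.01  # no evidence against flatness


def test_age_profile_empty_errors():
    with pytest.raises(ValueError):
        g.insertion_age_profile([], 1e6)
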