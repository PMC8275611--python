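"""Bisulfite methylome statistics: context calling, level aggregation,
conversion-efficiency control, DMR calling and compartment GC content.

Site calls arrive as CX-report-style tables (one row per covered cytosine
with methylated / unmethylated read counts).  The methylation level of a
site is n_meth / n_total; aggregate levels are read-weighted by default
(sum of methylated reads over sum of covering reads), matching the
per-site ratio definition.  DMRs are runs of consecutive shared sites with
consistent sign whose mean level difference exceeds 0.1, tested by
rank-sum with Benjamini-Hochberg correction.  GC statistics per genomic
compartment link methylation to deamination-driven GC erosion.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io_core import FeatureRecord, Genome, get_logger

__all__ = [
    "Dmr",
    "call_context",
    "scan_cytosines",
    "methylation_level",
    "site_levels",
    "estimate_conversion_rate",
    "window_levels",
    "call_dmrs",
    "annotate_regions",
    "compartment_gc",
]

_LOG = get_logger("genodyn.methyl")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


# ---------------------------------------------------------------------------
# Context calling
# ---------------------------------------------------------------------------

def call_context(
    genome: Genome, scaffold_id: str, position: int, strand: str
) -> str | None:
    """CG/CHG/CHH context of a cytosine; None when the two-base downstream
    window is truncated by the scaffold end or contains N.

    On the plus strand the base at ``position`` must be C; on the minus
    strand it must be G (a minus-strand cytosine) and the window is read
    upstream in reverse complement.
    """
    seq = genome.scaffolds[scaffold_id]
    if strand == "+":
        if seq[position] != "C":
            raise ValueError(
                f"{scaffold_id}:{position}+ is {seq[position]}, not a cytosine"
            )
        if position + 2 >= len(seq):
            return None
        b1, b2 = seq[position + 1], seq[position + 2]
    elif strand == "-":
        if seq[position] != "G":
            raise ValueError(
                f"{scaffold_id}:{position}- is {seq[position]}, "
                "not a minus-strand cytosine"
            )
        if position - 2 < 0:
            return None
        b1 = seq[position - 1].translate(_COMPLEMENT)
        b2 = seq[position - 2].translate(_COMPLEMENT)
    else:
        raise ValueError(f"bad strand {strand!r}")
    if "N" in (b1, b2):
        return None
    if b1 == "G":
        return "CG"
    if b2 == "G":
        return "CHG"
    return "CHH"


def scan_cytosines(genome: Genome) -> pd.DataFrame:
    """All context-callable cytosines on both strands, vectorized.

    Returns a DataFrame with scaffold_id, position (0-based), strand,
    context and trinucleotide, ordered by scaffold and position.
    """
    frames = []
    for sid, seq in genome.scaffolds.items():
        arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
        n = arr.size
        if n < 3:
            continue
        is_c = arr == ord("C")
        is_g = arr == ord("G")
        is_n = arr == ord("N")

        # plus strand: C at i, window i+1, i+2
        pos = np.nonzero(is_c[: n - 2])[0]
        b1, b2 = arr[pos + 1], arr[pos + 2]
        ok = ~(np.isin(b1, ord("N")) | np.isin(b2, ord("N")))
        pos, b1, b2 = pos[ok], b1[ok], b2[ok]
        ctx_plus = np.where(
            b1 == ord("G"), "CG", np.where(b2 == ord("G"), "CHG", "CHH")
        )
        tri_plus = [seq[p: p + 3] for p in pos]
        frames.append(
            pd.DataFrame(
                {
                    "scaffold_id": sid, "position": pos, "strand": "+",
                    "context": ctx_plus, "trinucleotide": tri_plus,
                }
            )
        )

        # minus strand: G at i, window i-1, i-2 (complemented)
        posm = np.nonzero(is_g[2:])[0] + 2
        c1 = arr[posm - 1]
        c2 = arr[posm - 2]
        ok = ~(np.isin(c1, ord("N")) | np.isin(c2, ord("N")))
        posm, c1, c2 = posm[ok], c1[ok], c2[ok]
        # complement: G->C pairing means context base is G iff genomic base is C
        ctx_minus = np.where(
            c1 == ord("C"), "CG", np.where(c2 == ord("C"), "CHG", "CHH")
        )
        tri_minus = [
            seq[p - 2: p + 1][::-1].translate(_COMPLEMENT) for p in posm
        ]
        frames.append(
            pd.DataFrame(
                {
                    "scaffold_id": sid, "position": posm, "strand": "-",
                    "context": ctx_minus, "trinucleotide": tri_minus,
                }
            )
        )
    if not frames:
        return pd.DataFrame(
            columns=["scaffold_id", "position", "strand", "context", "trinucleotide"]
        )
    out = pd.concat(frames, ignore_index=True)
    return out.sort_values(["scaffold_id", "position", "strand"]).reset_index(drop=True)


# ---------------------------------------------------------------------------
# Levels
# ---------------------------------------------------------------------------

def site_levels(calls: pd.DataFrame) -> pd.Series:
    total = calls["count_methylated"] + calls["count_unmethylated"]
    return calls["count_methylated"] / total


def methylation_level(
    calls: pd.DataFrame,
    min_coverage: int = 1,
    site_averaged: bool = False,
) -> float:
    """Aggregate methylation level of a group of site calls.

    Read-weighted by default: sum of methylated reads over sum of covering
    reads.  ``site_averaged`` instead averages per-site ratios.  Returns
    NaN for an empty/uncovered group (reported as missing).
    """
    total = calls["count_methylated"] + calls["count_unmethylated"]
    keep = total >= min_coverage
    calls, total = calls[keep], total[keep]
    if len(calls) == 0 or total.sum() == 0:
        return float("nan")
    if site_averaged:
        return float((calls["count_methylated"] / total).mean())
    return float(calls["count_methylated"].sum() / total.sum())


def estimate_conversion_rate(control_calls: pd.DataFrame) -> float:
    """Bisulfite conversion efficiency from an unmethylated spike-in control:
    1 minus the apparent methylation of the control."""
    total = (
        control_calls["count_methylated"] + control_calls["count_unmethylated"]
    ).sum()
    if total == 0:
        raise ValueError("no covered control sites")
    return 1.0 - control_calls["count_methylated"].sum() / total


def window_levels(
    calls: pd.DataFrame,
    window: int,
    scaffold_lengths: Mapping[str, int],
    contexts: Sequence[str] = ("CG", "CHG", "CHH"),
    min_coverage: int = 1,
) -> pd.DataFrame:
    """Read-weighted levels in tiling windows, per context.

    Every window of every scaffold appears for every requested context;
    windows with no covered sites report NaN.
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    rows = []
    grouped = dict(tuple(calls.groupby("scaffold_id")))
    for sid, length in scaffold_lengths.items():
        sub = grouped.get(sid)
        edges = list(range(0, length, window)) or [0]
        for start in edges:
            end = min(start + window, length)
            for ctx in contexts:
                level = float("nan")
                if sub is not None:
                    in_win = sub[
                        (sub["position"] >= start)
                        & (sub["position"] < end)
                        & (sub["context"] == ctx)
                    ]
                    level = methylation_level(in_win, min_coverage=min_coverage)
                rows.append(
                    {
                        "scaffold_id": sid, "start": start, "end": end,
                        "context": ctx, "level": level,
                    }
                )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# DMR calling
# ---------------------------------------------------------------------------

@dataclass
class Dmr:
    scaffold_id: str
    start: int
    end: int
    context: str
    mean_a: float
    mean_b: float
    mean_diff: float
    n_sites: int
    p_value: float
    q_value: float


def _segment_runs(
    pos: np.ndarray,
    diff: np.ndarray,
    min_sites: int,
    min_diff: float,
    max_spacing: int,
) -> list[tuple[int, int]]:
    """Index slices [i, j) of maximal candidate runs: consecutive sites with
    spacing <= max_spacing, consistent nonzero sign, run mean |diff| > min_diff."""
    n = len(pos)
    if n == 0:
        return []
    sign = np.sign(diff)
    breaks = np.zeros(n, dtype=bool)
    breaks[0] = True
    if n > 1:
        breaks[1:] = (
            (np.diff(pos) > max_spacing)
            | (sign[1:] != sign[:-1])
            | (sign[1:] == 0)
            | (sign[:-1] == 0)
        )
    run_id = np.cumsum(breaks)
    out: list[tuple[int, int]] = []
    boundaries = np.flatnonzero(breaks).tolist() + [n]
    for i, j in zip(boundaries[:-1], boundaries[1:]):
        if j - i >= min_sites and sign[i] != 0 and abs(diff[i:j].mean()) > min_diff:
            out.append((i, j))
    return out


def _ranksum_stat(level_a: np.ndarray, level_b: np.ndarray) -> float:
    try:
        stat, _p = stats.ranksums(level_a, level_b)
    except ValueError:
        return 0.0
    return abs(float(stat))


def call_dmrs(
    calls_a: pd.DataFrame,
    calls_b: pd.DataFrame,
    context: str,
    min_diff: float = 0.1,
    min_sites: int = 5,
    max_spacing: int = 300,
    alpha: float = 0.05,
    min_coverage: int = 1,
    n_permutations: int = 100,
    seed: int = 0,
    return_candidate_count: bool = False,
):
    """Differentially methylated regions between two groups of site calls.

    Candidates are maximal runs of >= ``min_sites`` consecutive shared
    sites (spacing <= ``max_spacing``) whose per-site level differences
    share a sign, with run mean |difference| strictly above ``min_diff``.
    Each candidate is scored by the rank-sum statistic on per-site levels.
    Because candidates are selected on the same data they are tested on, a
    naive rank-sum p-value is anti-conservative; significance is therefore
    calibrated against a permutation null in which per-site group labels
    are flipped at random and the segmentation re-run — a candidate's
    p-value is the fraction of permutations whose best candidate statistic
    matches or beats it.  Benjamini-Hochberg controls FDR at ``alpha``.
    """
    a = calls_a[calls_a["context"] == context].copy()
    b = calls_b[calls_b["context"] == context].copy()
    if a.empty and not calls_a.empty and calls_a["context"].nunique() == 1:
        raise ValueError(
            f"context mismatch: requested {context}, "
            f"group A holds {calls_a['context'].unique().tolist()}"
        )
    for df in (a, b):
        df["total"] = df["count_methylated"] + df["count_unmethylated"]
    a = a[a["total"] >= min_coverage]
    b = b[b["total"] >= min_coverage]
    merged = a.merge(
        b,
        on=["scaffold_id", "position", "strand"],
        suffixes=("_a", "_b"),
    )
    if merged.empty:
        return ([], 0) if return_candidate_count else []
    merged["level_a"] = merged["count_methylated_a"] / merged["total_a"]
    merged["level_b"] = merged["count_methylated_b"] / merged["total_b"]
    merged = merged.sort_values(["scaffold_id", "position"]).reset_index(drop=True)

    per_scaffold = [
        (
            sid,
            sub["position"].to_numpy(),
            sub["level_a"].to_numpy(),
            sub["level_b"].to_numpy(),
        )
        for sid, sub in merged.groupby("scaffold_id", sort=True)
    ]

    candidates: list[tuple[str, np.ndarray, np.ndarray, np.ndarray, float]] = []
    for sid, pos, la, lb in per_scaffold:
        for i, j in _segment_runs(pos, la - lb, min_sites, min_diff, max_spacing):
            stat = _ranksum_stat(la[i:j], lb[i:j])
            candidates.append((sid, pos[i:j], la[i:j], lb[i:j], stat))
    if not candidates:
        return ([], 0) if return_candidate_count else []

    # permutation null: flip each site's labels at random, re-segment, and
    # record the best candidate statistic per permutation (0 when none)
    rng = np.random.default_rng(seed)
    null_max = np.zeros(n_permutations)
    for k in range(n_permutations):
        best = 0.0
        for _sid, pos, la, lb in per_scaffold:
            flip = rng.random(len(pos)) < 0.5
            pa = np.where(flip, lb, la)
            pb = np.where(flip, la, lb)
            for i, j in _segment_runs(pos, pa - pb, min_sites, min_diff, max_spacing):
                best = max(best, _ranksum_stat(pa[i:j], pb[i:j]))
        null_max[k] = best

    # the max-statistic null is already familywise-adjusted across candidates
    # (each candidate is compared to the best score the whole permuted genome
    # can produce), so the permutation p doubles as the adjusted q
    p_values = [
        (1.0 + float(np.sum(null_max >= stat))) / (1.0 + n_permutations)
        for *_rest, stat in candidates
    ]
    q_values = p_values
    dmrs: list[Dmr] = []
    for (sid, pos, la, lb, _stat), p, q in zip(candidates, p_values, q_values):
        if q > alpha:
            continue
        dmrs.append(
            Dmr(
                scaffold_id=sid,
                start=int(pos.min()),
                end=int(pos.max()) + 1,
                context=context,
                mean_a=float(la.mean()),
                mean_b=float(lb.mean()),
                mean_diff=float((la - lb).mean()),
                n_sites=len(pos),
                p_value=float(p),
                q_value=float(q),
            )
        )
    _LOG.info(
        "DMR calling (%s): %d candidates, %d significant at q<=%.3g",
        context, len(candidates), len(dmrs), alpha,
    )
    return (dmrs, len(candidates)) if return_candidate_count else dmrs


# ---------------------------------------------------------------------------
# Region annotation and compartment GC
# ---------------------------------------------------------------------------

def _interval_overlap(
    start: int, end: int, intervals: Sequence[tuple[int, int]]
) -> int:
    covered = 0
    for s, e in intervals:
        covered += max(0, min(end, e) - max(start, s))
    return covered


def _class_intervals(
    features: Sequence[FeatureRecord],
    scaffold_lengths: Mapping[str, int],
) -> dict[str, dict[str, list[tuple[int, int]]]]:
    """Partition intervals per scaffold: exonic, intronic, intergenic, plus
    the TE overlay.  Intergenic is the complement of gene spans."""
    per: dict[str, dict[str, list[tuple[int, int]]]] = {
        "exonic": {}, "intronic": {}, "gene": {}, "TE": {},
    }
    for rec in features:
        key = {
            "exon": "exonic", "intron": "intronic",
            "gene": "gene", "TE": "TE", "LTR_element": "TE",
        }.get(rec.feature_class)
        if key:
            per[key].setdefault(rec.scaffold_id, []).append((rec.start, rec.end))
    out: dict[str, dict[str, list[tuple[int, int]]]] = {
        "exonic": per["exonic"], "intronic": per["intronic"], "TE": per["TE"],
        "intergenic": {},
    }
    for sid, length in scaffold_lengths.items():
        spans = sorted(per["gene"].get(sid, []))
        inter: list[tuple[int, int]] = []
        cursor = 0
        for s, e in spans:
            if s > cursor:
                inter.append((cursor, s))
            cursor = max(cursor, e)
        if cursor < length:
            inter.append((cursor, length))
        out["intergenic"][sid] = inter
    return out


def annotate_regions(
    regions: Sequence[tuple[str, int, int]],
    features: Sequence[FeatureRecord],
    scaffold_lengths: Mapping[str, int],
) -> tuple[pd.DataFrame, dict[str, float]]:
    """Fractional overlap of regions with genomic compartments.

    Each region gets exonic/intronic/intergenic fractions (a partition of
    its bases) and, separately, a TE fraction.  The summary reports the
    proportion of regions assigned (by majority base overlap) to each
    partition class, and of region-bases per class including TE.
    """
    classes = _class_intervals(features, scaffold_lengths)
    partition = ("exonic", "intronic", "intergenic")
    rows = []
    for sid, start, end in regions:
        length = end - start
        row: dict[str, object] = {"scaffold_id": sid, "start": start, "end": end}
        for cls in partition + ("TE",):
            ov = _interval_overlap(start, end, classes[cls].get(sid, []))
            row[cls] = ov / length if length else 0.0
        rows.append(row)
    df = pd.DataFrame(
        rows, columns=["scaffold_id", "start", "end", *partition, "TE"]
    )
    summary: dict[str, float] = {}
    if len(df):
        majority = df[list(partition)].idxmax(axis=1)
        lengths = df["end"] - df["start"]
        for cls in partition:
            summary[f"regions_{cls}"] = float((majority == cls).mean())
            summary[f"bases_{cls}"] = float(
                (df[cls] * lengths).sum() / lengths.sum()
            )
        summary["regions_TE"] = float((df["TE"] > 0.5).mean())
        summary["bases_TE"] = float((df["TE"] * lengths).sum() / lengths.sum())
    return df, summary


def compartment_gc(
    genome: Genome,
    intervals_by_class: Mapping[str, Mapping[str, Sequence[tuple[int, int]]]],
) -> dict[str, float]:
    """GC fraction per compartment class: (G+C)/(A+C+G+T) over the class's
    intervals, with N excluded entirely.  Classes with zero non-N bases are
    reported as NaN (missing)."""
    out: dict[str, float] = {}
    for cls, per_scaffold in intervals_by_class.items():
        gc = total = 0
        for sid, intervals in per_scaffold.items():
            seq = genome.scaffolds[sid]
            for s, e in intervals:
                chunk = seq[s:e]
                gc += chunk.count("G") + chunk.count("C")
                total += len(chunk) - chunk.count("N")
        out[cls] = gc / total if total else float("nan")
    return out
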