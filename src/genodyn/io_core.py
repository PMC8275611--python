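"""Readers/writers, in-memory genome model, coordinates, configuration, logging.

All internal coordinates are 0-based half-open on the plus strand.  The
1-based closed conventions of GFF3 and the 12-column tabular hit dialect are
converted at the I/O boundary, in exactly one place each, so that interval
arithmetic elsewhere in the package never has to think about off-by-one.
"""

from __future__ import annotations

import logging
import sys
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "Genome",
    "GapRegistry",
    "FeatureRecord",
    "HitRecord",
    "read_fasta",
    "write_fasta",
    "find_assembly_gaps",
    "read_gff3",
    "write_gff3",
    "read_hit_table",
    "write_hit_table",
    "read_cx_report",
    "write_cx_report",
    "read_bed",
    "write_bed",
    "read_config",
    "write_config",
    "get_logger",
    "DEFAULTS",
]

class SaturationError(ValueError):
    """A corrected distance is undefined because divergence has saturated
    (the logarithm's argument is non-positive, or p >= 3/4 for Jukes-Cantor)."""


# ---------------------------------------------------------------------------
# Configuration and logging
# ---------------------------------------------------------------------------

#: Every analysis threshold, under a stable name, with the published value
#: (or this package's documented choice) as default.  A flat key/value
#: config file can override any of them.
DEFAULTS: dict[str, float | int | str] = {
    # LTR lifecycle
    "ltr.rate_r": 2.2e-9,            # substitutions/site/year (gnetophyte-scale clock)
    "ltr.rate_r_amborella": 1.8e-8,  # alternative clock used for Amborella
    "ltr.truncated_min_coverage": 0.8,
    "ltr.truncated_min_identity": 0.6,
    "solo.min_coverage": 0.7,
    "solo.min_identity": 0.7,
    "solo.edge_distance": 5000,      # bases from scaffold end, filter (b)
    "solo.gap_distance": 500,        # bases from an N gap, filter (d)
    "gaps.min_run": 10,              # minimum N run that counts as an assembly gap
    # pairwise alignment (affine-gap global DP)
    "align.match": 5,
    "align.mismatch": -4,
    "align.gap_open": -10,
    "align.gap_extend": -1,
    # Ks / WGD
    "ks.evalue_cutoff": 1e-10,
    "ks.family_method": "components",
    "ks.mcl_inflation": 1.5,
    "ks.subfamily_threshold": 5.0,
    "ks.range_low": 0.05,
    "ks.range_high": 5.0,
    "ks.n_bootstrap": 200,
    "ks.peak_prominence": 0.10,      # fraction of global density maximum
    "ks.ci_level": 0.90,
    "ks.dating_window_low": 0.7,
    "ks.dating_window_high": 1.25,
    # collinearity
    "collinear.c_score": 0.5,
    "collinear.min_anchors": 5,
    "collinear.max_gap": 15,         # genes
    "collinear.tandem_window": 5,    # ranks
    "collinear.synteny_window": 15,  # genes
    "collinear.synteny_min_shared": 5,
    # methylome
    "methyl.min_coverage": 1,
    "methyl.dmr_min_diff": 0.1,
    "methyl.dmr_min_sites": 5,
    "methyl.dmr_max_spacing": 300,
    "methyl.dmr_alpha": 0.05,
    "methyl.window": 1_000_000,
}


def get_logger(name: str = "genodyn", level: str | int = "INFO") -> logging.Logger:
    """Package logger; stages log input counts, per-rule rejection counts and
    output counts so accounting tables can be rebuilt from a run's log."""
    logger = logging.getLogger(name)
    if not logger.handlers:
        handler = logging.StreamHandler(sys.stderr)
        handler.setFormatter(
            logging.Formatter("%(asctime)s %(name)s %(levelname)s %(message)s")
        )
        logger.addHandler(handler)
    logger.setLevel(level)
    return logger


_LOG = get_logger("genodyn.io")


def _coerce(value: str) -> float | int | str:
    for cast in (int, float):
        try:
            return cast(value)
        except ValueError:
            continue
    return value


def read_config(
    path: str | Path, include_defaults: bool = True
) -> dict[str, float | int | str]:
    """Read a flat ``key = value`` config file; '#' starts a comment.

    Returns DEFAULTS overlaid with the file's entries (or the file's
    entries alone with ``include_defaults=False``).
    """
    config = dict(DEFAULTS) if include_defaults else {}
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ValueError(f"{path}:{lineno}: expected 'key = value', got {raw!r}")
        key, _, value = line.partition("=")
        config[key.strip()] = _coerce(value.strip())
    return config


def write_config(config: Mapping[str, object], path: str | Path) -> None:
    with open(path, "w") as fh:
        for key in sorted(config):
            fh.write(f"{key} = {config[key]}\n")


# ---------------------------------------------------------------------------
# Genome model
# ---------------------------------------------------------------------------

_VALID = set("ACGTN")


@dataclass
class Genome:
    """Assembled nucleotide scaffolds, uppercase over the {A,C,G,T,N} alphabet.

    ``scaffolds`` preserves input order (dicts are ordered).
    """

    scaffolds: dict[str, str] = field(default_factory=dict)

    @property
    def lengths(self) -> dict[str, int]:
        return {sid: len(seq) for sid, seq in self.scaffolds.items()}

    def __len__(self) -> int:
        return len(self.scaffolds)

    def validate(self) -> None:
        for sid, seq in self.scaffolds.items():
            if not sid:
                raise ValueError("empty scaffold id")
            bad = set(seq) - _VALID
            if bad:
                raise ValueError(f"scaffold {sid}: invalid characters {sorted(bad)}")


def _normalize_sequence(raw: str, record_id: str) -> str:
    """Uppercase, U→T; anything outside {A,C,G,T,N} becomes N with a warning."""
    seq = raw.upper().replace("U", "T")
    bad = set(seq) - _VALID
    if bad:
        _LOG.warning(
            "record %s: %d non-ACGTN character kinds (%s) mapped to N",
            record_id, len(bad), "".join(sorted(bad)),
        )
        seq = "".join(c if c in _VALID else "N" for c in seq)
    return seq


def read_fasta(path: str | Path) -> Genome:
    """Read a FASTA file into a :class:`Genome`.

    Record order is preserved; sequences are normalized (case, U→T, other
    characters to N).  Duplicate ids and empty files are errors.
    """
    genome = Genome()
    for record in SeqIO.parse(str(path), "fasta"):
        if record.id in genome.scaffolds:
            raise ValueError(f"duplicate id {record.id}")
        genome.scaffolds[record.id] = _normalize_sequence(str(record.seq), record.id)
    if not genome.scaffolds:
        raise ValueError(f"empty FASTA file: {path}")
    return genome


def write_fasta(genome: Genome, path: str | Path) -> None:
    """Write scaffolds wrapped at 60 columns (Bio.SeqIO default)."""
    records = [
        SeqRecord(Seq(seq), id=sid, description="")
        for sid, seq in genome.scaffolds.items()
    ]
    SeqIO.write(records, str(path), "fasta")


# ---------------------------------------------------------------------------
# Assembly gaps
# ---------------------------------------------------------------------------

@dataclass
class GapRegistry:
    """Maximal N runs of length >= min_run, 0-based half-open, sorted."""

    intervals: list[tuple[str, int, int]] = field(default_factory=list)
    min_run: int = 1

    def for_scaffold(self, scaffold_id: str) -> list[tuple[int, int]]:
        return [(s, e) for sid, s, e in self.intervals if sid == scaffold_id]


def find_assembly_gaps(genome: Genome, min_run: int) -> GapRegistry:
    """Locate maximal runs of N of length >= ``min_run`` on every scaffold."""
    if min_run < 1:
        raise ValueError(f"min_run must be >= 1, got {min_run}")
    intervals: list[tuple[str, int, int]] = []
    for sid, seq in genome.scaffolds.items():
        i, n = 0, len(seq)
        while i < n:
            if seq[i] == "N":
                j = i
                while j < n and seq[j] == "N":
                    j += 1
                if j - i >= min_run:
                    intervals.append((sid, i, j))
                i = j
            else:
                i += 1
    return GapRegistry(intervals=intervals, min_run=min_run)


# ---------------------------------------------------------------------------
# Features (GFF3)
# ---------------------------------------------------------------------------

FEATURE_CLASSES = {
    "gene", "exon", "intron", "TE", "LTR_element", "LTR_terminus", "intergenic",
}


@dataclass
class FeatureRecord:
    """One annotated interval, 0-based half-open internally."""

    scaffold_id: str
    start: int
    end: int
    strand: str = "."
    feature_class: str = "gene"
    id: str = ""
    attributes: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"feature {self.id or '?'}: bad interval [{self.start}, {self.end})"
            )
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"feature {self.id or '?'}: bad strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start


def _fmt_attributes(rec: FeatureRecord) -> str:
    parts = []
    if rec.id:
        parts.append(f"ID={rec.id}")
    parts.extend(f"{k}={v}" for k, v in rec.attributes.items() if k != "ID")
    return ";".join(parts) if parts else "."


def read_gff3(path: str | Path) -> list[FeatureRecord]:
    """Parse GFF3 (1-based closed) into internal 0-based half-open records.

    Feature types outside the supported vocabulary are kept, recorded under
    ``attributes['source_type']`` with feature_class 'gene' left untouched
    only for genes; unknown types get feature_class equal to the raw type so
    the paired writer round-trips them.
    """
    records: list[FeatureRecord] = []
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        if not raw.strip() or raw.startswith("#"):
            continue
        cols = raw.rstrip("\n").split("\t")
        if len(cols) != 9:
            raise ValueError(f"{path}:{lineno}: expected 9 columns, got {len(cols)}")
        sid, _source, ftype, start_s, end_s, _score, strand, _frame, attrs_s = cols
        start1, end1 = int(start_s), int(end_s)
        if start1 > end1:
            raise ValueError(f"{path}:{lineno}: start {start1} > end {end1}")
        attributes: dict[str, str] = {}
        if attrs_s not in (".", ""):
            for item in attrs_s.split(";"):
                if not item:
                    continue
                key, _, value = item.partition("=")
                attributes[key] = value
        rec_id = attributes.pop("ID", "")
        records.append(
            FeatureRecord(
                scaffold_id=sid,
                start=start1 - 1,       # the single 1-based → 0-based conversion
                end=end1,
                strand=strand,
                feature_class=ftype,
                id=rec_id,
                attributes=attributes,
            )
        )
    return records


def write_gff3(records: Iterable[FeatureRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for rec in records:
            fh.write(
                "\t".join(
                    (
                        rec.scaffold_id,
                        "genodyn",
                        rec.feature_class,
                        str(rec.start + 1),   # 0-based → 1-based at the boundary
                        str(rec.end),
                        ".",
                        rec.strand,
                        ".",
                        _fmt_attributes(rec),
                    )
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# Similarity hit tables (12-column tabular dialect)
# ---------------------------------------------------------------------------

HIT_COLUMNS = [
    "query_id", "subject_id", "pct_identity", "aln_length", "mismatches",
    "gap_opens", "q_start", "q_end", "s_start", "s_end", "e_value", "bit_score",
]


@dataclass
class HitRecord:
    """One row of the 12-column tabular similarity dialect.

    q/s coordinates stay 1-based inclusive as in the format; use
    :meth:`subject_interval` for the 0-based half-open genomic interval.
    """

    query_id: str
    subject_id: str
    pct_identity: float
    aln_length: int
    mismatches: int
    gap_opens: int
    q_start: int
    q_end: int
    s_start: int
    s_end: int
    e_value: float
    bit_score: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.pct_identity <= 100.0):
            raise ValueError(
                f"hit {self.query_id}->{self.subject_id}: "
                f"pct_identity {self.pct_identity} outside [0, 100]"
            )
        if self.aln_length < 1:
            raise ValueError(
                f"hit {self.query_id}->{self.subject_id}: aln_length < 1"
            )
        if self.e_value < 0:
            raise ValueError(
                f"hit {self.query_id}->{self.subject_id}: negative e-value"
            )

    def subject_interval(self) -> tuple[int, int]:
        """Subject interval as 0-based half-open, strand-normalized."""
        lo, hi = sorted((self.s_start, self.s_end))
        return lo - 1, hi


def read_hit_table(path: str | Path) -> list[HitRecord]:
    """Read a 12-column tab-separated hit table, preserving row order."""
    records: list[HitRecord] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            if not raw.strip() or raw.startswith("#"):
                continue
            cols = raw.rstrip("\n").split("\t")
            if len(cols) != 12:
                raise ValueError(
                    f"{path}:{lineno}: expected 12 columns, got {len(cols)}"
                )
            try:
                rec = HitRecord(
                    query_id=cols[0],
                    subject_id=cols[1],
                    pct_identity=float(cols[2]),
                    aln_length=int(cols[3]),
                    mismatches=int(cols[4]),
                    gap_opens=int(cols[5]),
                    q_start=int(cols[6]),
                    q_end=int(cols[7]),
                    s_start=int(cols[8]),
                    s_end=int(cols[9]),
                    e_value=float(cols[10]),
                    bit_score=float(cols[11]),
                )
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from exc
            records.append(rec)
    return records


def write_hit_table(records: Iterable[HitRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for r in records:
            fh.write(
                "\t".join(
                    str(v)
                    for v in (
                        r.query_id, r.subject_id, r.pct_identity, r.aln_length,
                        r.mismatches, r.gap_opens, r.q_start, r.q_end,
                        r.s_start, r.s_end, r.e_value, r.bit_score,
                    )
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# CX-report methylation tables
# ---------------------------------------------------------------------------

CX_COLUMNS = [
    "scaffold_id", "position", "strand", "count_methylated",
    "count_unmethylated", "context", "trinucleotide",
]


def read_cx_report(path: str | Path) -> pd.DataFrame:
    """Read a CX-report-style TSV into a DataFrame with 0-based positions.

    File positions are 1-based (as emitted by bisulfite callers); the
    returned ``position`` column is 0-based.
    """
    df = pd.read_csv(
        path, sep="\t", names=CX_COLUMNS, header=None,
        dtype={
            "scaffold_id": str, "position": int, "strand": str,
            "count_methylated": int, "count_unmethylated": int,
            "context": str, "trinucleotide": str,
        },
    )
    if (df["count_methylated"] < 0).any() or (df["count_unmethylated"] < 0).any():
        raise ValueError(f"{path}: negative read counts")
    df["position"] = df["position"] - 1
    return df


def write_cx_report(df: pd.DataFrame, path: str | Path) -> None:
    out = df[CX_COLUMNS].copy()
    out["position"] = out["position"] + 1
    out.to_csv(path, sep="\t", header=False, index=False)


# ---------------------------------------------------------------------------
# BED (gaps, DMRs)
# ---------------------------------------------------------------------------

def read_bed(path: str | Path) -> list[tuple[str, int, int, str]]:
    """Read BED3/BED4 (already 0-based half-open); returns (sid, start, end, name)."""
    rows: list[tuple[str, int, int, str]] = []
    with open(path) as fh:
        for raw in fh:
            if not raw.strip() or raw.startswith(("#", "track", "browser")):
                continue
            cols = raw.rstrip("\n").split("\t")
            name = cols[3] if len(cols) > 3 else ""
            rows.append((cols[0], int(cols[1]), int(cols[2]), name))
    return rows


def write_bed(rows: Iterable[tuple], path: str | Path) -> None:
    with open(path, "w") as fh:
        for row in rows:
            fh.write("\t".join(str(v) for v in row) + "\n")
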