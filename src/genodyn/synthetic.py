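"""Synthetic genomes with known ground truth for every analysis stage.

The generator emulates the statistical structure the analyses assume:

* a single WGD producing collinear duplicate gene blocks on distinct
  scaffolds, whose pairwise synonymous divergence is drawn from a
  lognormal around a target Ks depth and realized by placing substitutions
  only at synonymous positions until the Nei-Gojobori Ks reaches the draw;
* an LTR-retrotransposon landscape of intact, truncated, solo and
  non-autonomous copies whose LTR pairs diverge as d = 2 r T under a
  two-parameter (transition-biased) substitution process, plus decoy solo
  candidates that each violate exactly one detection filter (scaffold
  edge, assembly gap, coverage/identity, truncated overlap);
* compartmentalized cytosine methylation (gene / TE / intergenic by
  CG / CHG / CHH) with beta-distributed site levels, Poisson coverage,
  binomial read counts, imperfect bisulfite conversion, an unmethylated
  lambda-like spike-in control, and optional deamination of methylated
  cytosines toward thymine;
* a non-WGD outgroup genome carrying single-copy versions of every
  duplicated block, so 2:1 multiplicon ratios have a ground truth.

One root seed drives everything; each stage derives an independent
substream keyed by its name, so adding a stage never perturbs the draws
of earlier stages.
"""

from __future__ import annotations

import math
import zlib
from dataclasses import dataclass, field, asdict
from importlib import resources
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io_core import (
    FeatureRecord,
    GapRegistry,
    Genome,
    HitRecord,
    find_assembly_gaps,
    get_logger,
    read_config,
    write_config,
    write_fasta,
    write_gff3,
    write_hit_table,
    write_cx_report,
)
from .kswgd import _syn_sites, _pathway_counts, _jc_correct, _STOPS, _translate
from .ltr import DomainHit
from .methylome import scan_cytosines

__all__ = [
    "ScenarioConfig",
    "WgdConfig",
    "LtrConfig",
    "AgeDistribution",
    "DecoyConfig",
    "MethylomeConfig",
    "TruthTable",
    "GenomeBundle",
    "stage_rng",
    "random_sequence",
    "evolve_sequence",
    "simulate_wgd_paralogs",
    "plant_ltr_landscape",
    "simulate_methylome",
    "apply_deamination",
    "generate_scenario",
    "load_preset",
    "wgd_preset",
]

_LOG = get_logger("genodyn.synthetic")


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

@dataclass
class WgdConfig:
    ks_mean: float = 1.0          # arithmetic mean of the lognormal Ks depth
    ks_sd: float = 0.15
    n_retained_pairs: int = 200
    block_size: int = 25          # genes per collinear block
    n_blocks: int = 8
    cds_codons: int = 200
    shuffle_fraction: float = 0.0  # fraction of duplicate blocks order-shuffled
    n_noise_hits: int = 20         # weak similarity rows above the e-value cutoff
    outgroup_divergence: float = 0.05  # nucleotide divergence of the outgroup copies


@dataclass
class AgeDistribution:
    mode: str = "uniform"          # uniform | burst
    t_min: float = 0.5e6           # years
    t_max: float = 2.0e6
    burst_time: float = 1.5e6
    burst_sd: float = 0.4e6


@dataclass
class LtrConfig:
    n_intact: int = 60
    n_truncated: int = 20
    n_solo: int = 100
    n_nonautonomous: int = 20
    ltr_length: int = 5000
    internal_length: int = 5000
    age_distribution: AgeDistribution = field(default_factory=AgeDistribution)
    rate_r: float = 2.2e-9         # substitutions/site/year
    kappa: float = 2.0             # transition/transversion rate ratio


@dataclass
class DecoyConfig:
    n_edge_solo: int = 5
    n_gap_adjacent_solo: int = 5
    n_low_identity_solo: int = 5
    n_truncated_overlap_solo: int = 5

    @property
    def total(self) -> int:
        return (self.n_edge_solo + self.n_gap_adjacent_solo
                + self.n_low_identity_solo + self.n_truncated_overlap_solo)


#: (beta_mean, beta_concentration) per compartment x context; the defaults
#: echo a heavily methylated gymnosperm-like genome where TE and intergenic
#: space carry most of the methylation, including unusually high CHH.
_DEFAULT_LEVELS: dict[tuple[str, str], tuple[float, float]] = {
    ("gene", "CG"): (0.60, 20.0), ("gene", "CHG"): (0.40, 20.0),
    ("gene", "CHH"): (0.15, 20.0),
    ("TE", "CG"): (0.90, 20.0), ("TE", "CHG"): (0.80, 20.0),
    ("TE", "CHH"): (0.40, 20.0),
    ("intergenic", "CG"): (0.80, 20.0), ("intergenic", "CHG"): (0.75, 20.0),
    ("intergenic", "CHH"): (0.35, 20.0),
}


@dataclass
class MethylomeConfig:
    levels: dict[tuple[str, str], tuple[float, float]] = field(
        default_factory=lambda: dict(_DEFAULT_LEVELS)
    )
    coverage_mean: float = 20.0
    conversion_failure: float = 0.005
    lambda_length: int = 48_502    # spike-in control length


@dataclass
class ScenarioConfig:
    seed: int = 1
    n_scaffolds: int = 12
    scaffold_length: int = 400_000
    gc_target: float = 0.35
    wgd: WgdConfig = field(default_factory=WgdConfig)
    ltr: LtrConfig = field(default_factory=LtrConfig)
    decoys: DecoyConfig = field(default_factory=DecoyConfig)
    methylome: MethylomeConfig = field(default_factory=MethylomeConfig)
    deamination_rate: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 < self.gc_target < 1.0:
            raise ValueError("gc_target must be in (0, 1)")
        if self.ltr.rate_r <= 0:
            raise ValueError("rate_r must be positive")
        for (comp, ctx), (mean, conc) in self.methylome.levels.items():
            if not 0.0 < mean < 1.0:
                raise ValueError(f"beta_mean for {comp}/{ctx} must be in (0, 1)")
            if conc <= 0:
                raise ValueError(f"beta_concentration for {comp}/{ctx} must be > 0")

    # -- flat key/value round trip ------------------------------------------
    def to_flat(self) -> dict[str, object]:
        flat: dict[str, object] = {
            "seed": self.seed, "n_scaffolds": self.n_scaffolds,
            "scaffold_length": self.scaffold_length, "gc_target": self.gc_target,
            "deamination_rate": self.deamination_rate,
        }
        for key, value in asdict(self.wgd).items():
            flat[f"wgd.{key}"] = value
        for key, value in asdict(self.ltr).items():
            if key == "age_distribution":
                for k2, v2 in value.items():
                    flat[f"ltr.age.{k2}"] = v2
            else:
                flat[f"ltr.{key}"] = value
        for key, value in asdict(self.decoys).items():
            flat[f"decoys.{key}"] = value
        for (comp, ctx), (mean, conc) in self.methylome.levels.items():
            flat[f"methylome.{comp}.{ctx}.mean"] = mean
            flat[f"methylome.{comp}.{ctx}.concentration"] = conc
        flat["methylome.coverage_mean"] = self.methylome.coverage_mean
        flat["methylome.conversion_failure"] = self.methylome.conversion_failure
        flat["methylome.lambda_length"] = self.methylome.lambda_length
        return flat

    @classmethod
    def from_flat(cls, flat: Mapping[str, object]) -> "ScenarioConfig":
        cfg = cls()
        wgd, ltr, age, decoys = {}, {}, {}, {}
        levels = dict(_DEFAULT_LEVELS)
        meth: dict[str, object] = {}
        for key, value in flat.items():
            if key.startswith("wgd."):
                wgd[key[4:]] = value
            elif key.startswith("ltr.age."):
                age[key[8:]] = value
            elif key.startswith("ltr."):
                ltr[key[4:]] = value
            elif key.startswith("decoys."):
                decoys[key[7:]] = value
            elif key.startswith("methylome."):
                parts = key.split(".")
                if len(parts) == 4:
                    comp, ctx, which = parts[1], parts[2], parts[3]
                    mean, conc = levels[(comp, ctx)]
                    if which == "mean":
                        levels[(comp, ctx)] = (float(value), conc)
                    else:
                        levels[(comp, ctx)] = (mean, float(value))
                else:
                    meth[parts[1]] = value
            elif hasattr(cfg, key):
                setattr(cfg, key, value)
        if age:
            base = asdict(cfg.ltr.age_distribution)
            base.update(age)
            ltr["age_distribution"] = AgeDistribution(**base)
        if wgd:
            cfg.wgd = WgdConfig(**{**asdict(cfg.wgd), **wgd})
        if ltr:
            defaults = asdict(cfg.ltr)
            defaults["age_distribution"] = cfg.ltr.age_distribution
            defaults.update(ltr)
            cfg.ltr = LtrConfig(**defaults)
        if decoys:
            cfg.decoys = DecoyConfig(**{**asdict(cfg.decoys), **decoys})
        cfg.methylome = MethylomeConfig(
            levels=levels,
            coverage_mean=float(meth.get("coverage_mean", cfg.methylome.coverage_mean)),
            conversion_failure=float(
                meth.get("conversion_failure", cfg.methylome.conversion_failure)
            ),
            lambda_length=int(meth.get("lambda_length", cfg.methylome.lambda_length)),
        )
        cfg.__post_init__()
        return cfg


def load_preset(name: str, seed: int | None = None) -> ScenarioConfig:
    """Load a packaged scenario preset; optionally override its seed."""
    ref = resources.files("genodyn") / "presets" / f"{name}.cfg"
    with resources.as_file(ref) as path:
        flat = read_config(path, include_defaults=False)
    cfg = ScenarioConfig.from_flat(flat)
    if seed is not None:
        cfg.seed = int(seed)
    return cfg


def wgd_preset(seed: int | None = None) -> ScenarioConfig:
    return load_preset("wgd_preset", seed=seed)


# ---------------------------------------------------------------------------
# Random substreams and sequence evolution
# ---------------------------------------------------------------------------

def stage_rng(seed: int, stage: str) -> np.random.Generator:
    """Independent substream for a named stage of the generator."""
    return np.random.default_rng([int(seed), zlib.crc32(stage.encode())])


_BASE_ARR = np.frombuffer(b"ACGT", dtype=np.uint8)
_TRANSITION = {ord("A"): ord("G"), ord("G"): ord("A"),
               ord("C"): ord("T"), ord("T"): ord("C")}
_TRANSVERSIONS = {
    ord("A"): (ord("C"), ord("T")), ord("G"): (ord("C"), ord("T")),
    ord("C"): (ord("A"), ord("G")), ord("T"): (ord("A"), ord("G")),
}


def random_sequence(length: int, gc: float, rng: np.random.Generator) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return rng.choice(_BASE_ARR, size=length, p=p).tobytes().decode("ascii")


def _k2p_site_probs(d: float, kappa: float) -> tuple[float, float]:
    """Exact per-site transition (P) and transversion (Q) probabilities of a
    two-parameter process run to expected divergence d with rate bias kappa."""
    beta_t = d / (kappa + 2.0)
    alpha_t = kappa * beta_t
    P = 0.25 + 0.25 * math.exp(-4.0 * beta_t) - 0.5 * math.exp(-2.0 * (alpha_t + beta_t))
    Q = 0.5 - 0.5 * math.exp(-4.0 * beta_t)
    return P, Q


def evolve_sequence(
    seq: str,
    divergence_d: float,
    kappa: float = 2.0,
    seed: int | np.random.Generator = 0,
) -> str:
    """Mutated copy of a sequence under a two-parameter substitution process.

    Each site is independently substituted with the exact transition /
    transversion probabilities of a process whose total expected number of
    substitutions per site is ``divergence_d`` with transition bias
    ``kappa``.  N sites are untouched.  Deterministic for a fixed seed.
    """
    if divergence_d < 0:
        raise ValueError(f"divergence must be non-negative, got {divergence_d}")
    if divergence_d == 0:
        return seq
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    P, Q = _k2p_site_probs(divergence_d, kappa)
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8).copy()
    u = rng.random(arr.size)
    pick = rng.integers(0, 2, size=arr.size)  # which transversion partner
    orig = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    valid = np.isin(orig, _BASE_ARR)
    do_ts = valid & (u < P)
    do_tv = valid & (u >= P) & (u < P + Q)
    for base in _BASE_ARR:
        m = do_ts & (orig == base)
        arr[m] = _TRANSITION[base]
    for base in _BASE_ARR:
        tv1, tv2 = _TRANSVERSIONS[base]
        m = do_tv & (orig == base)
        arr[m] = np.where(pick[m] == 0, tv1, tv2)
    return arr.tobytes().decode("ascii")


# ---------------------------------------------------------------------------
# WGD paralog simulation
# ---------------------------------------------------------------------------

_SENSE_CODONS = sorted(
    a + b + c
    for a in "ACGT" for b in "ACGT" for c in "ACGT"
    if (a + b + c) not in _STOPS
)


def random_cds(n_codons: int, rng: np.random.Generator) -> str:
    """Random in-frame CDS with no internal stop codons."""
    idx = rng.integers(0, len(_SENSE_CODONS), size=n_codons)
    return "".join(_SENSE_CODONS[i] for i in idx)


def _synonymous_alternatives(codon: str) -> list[tuple[int, str]]:
    """(position, base) single-nucleotide changes that preserve the amino acid
    and avoid stop codons."""
    aa = _translate(codon)
    out = []
    for pos in range(3):
        for base in "ACGT":
            if base == codon[pos]:
                continue
            alt = codon[:pos] + base + codon[pos + 1:]
            if alt not in _STOPS and _translate(alt) == aa:
                out.append((pos, base))
    return out


def _mutate_to_target_ks(
    cds: str, target_ks: float, rng: np.random.Generator, pair_name: str
) -> tuple[str, float]:
    """Apply synonymous substitutions to a copy of ``cds`` until its NG86 Ks
    against the original reaches ``target_ks``; returns (copy, realized Ks).

    Per-codon site and difference counts are maintained incrementally, so
    each step costs one codon re-evaluation.
    """
    n_codons = len(cds) // 3
    a_codons = [cds[3 * k: 3 * k + 3] for k in range(n_codons)]
    b_codons = list(a_codons)
    s_sites = np.array([_syn_sites(c) for c in a_codons])
    s_half = s_sites.copy()  # per-codon averaged S; updates as b changes
    sd = np.zeros(n_codons)
    nd = np.zeros(n_codons)

    def realized() -> float:
        S = s_half.sum()
        ps = sd.sum() / S if S > 0 else 0.0
        if ps >= 0.75:
            raise ValueError(
                f"pair {pair_name}: synonymous divergence saturated (ps={ps:.3f})"
            )
        return _jc_correct(ps, "ks")

    if target_ks <= 0:
        return cds, 0.0
    ks = 0.0
    max_steps = 60 * n_codons
    steps = 0
    while ks < target_ks:
        steps += 1
        if steps > max_steps:
            raise ValueError(
                f"pair {pair_name}: target Ks {target_ks:.3f} not reached after "
                f"{max_steps} substitutions (saturation)"
            )
        k = int(rng.integers(0, n_codons))
        options = _synonymous_alternatives(b_codons[k])
        if not options:
            continue
        pos, base = options[rng.integers(0, len(options))]
        b_codons[k] = b_codons[k][:pos] + base + b_codons[k][pos + 1:]
        s_half[k] = (s_sites[k] + _syn_sites(b_codons[k])) / 2.0
        sd[k], nd[k] = _pathway_counts(a_codons[k], b_codons[k])
        ks = realized()
    return "".join(b_codons), ks


def simulate_wgd_paralogs(
    cds_set: Sequence[str],
    ks_mean: float,
    ks_sd: float,
    n_retained_pairs: int,
    seed: int | np.random.Generator = 0,
) -> tuple[list[tuple[str, str]], list[float]]:
    """Duplicate each retained CDS to a target synonymous divergence.

    Targets are lognormal with arithmetic mean ``ks_mean`` and standard
    deviation ``ks_sd``; substitutions land only at synonymous positions
    until the realized NG86 Ks reaches the draw.  Returns the (original,
    duplicate) pairs and the realized Ks truth values.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if n_retained_pairs == 0:
        return [], []
    if len(cds_set) < n_retained_pairs:
        raise ValueError(
            f"need {n_retained_pairs} CDS, got {len(cds_set)}"
        )
    if ks_mean <= 0:
        targets = np.zeros(n_retained_pairs)
    else:
        sigma2 = math.log(1.0 + (ks_sd / ks_mean) ** 2)
        mu = math.log(ks_mean) - sigma2 / 2.0
        targets = rng.lognormal(mu, math.sqrt(sigma2), size=n_retained_pairs)
    pairs: list[tuple[str, str]] = []
    truth: list[float] = []
    for i in range(n_retained_pairs):
        cds = cds_set[i]
        if len(cds) % 3 != 0:
            raise ValueError(f"CDS {i} length not a multiple of 3")
        copy, realized = _mutate_to_target_ks(cds, float(targets[i]), rng, f"pair{i}")
        pairs.append((cds, copy))
        truth.append(realized)
    return pairs, truth


# ---------------------------------------------------------------------------
# Truth bookkeeping
# ---------------------------------------------------------------------------

@dataclass
class TruthTable:
    """Ground truth for every planted object, joinable to the emitted files."""

    elements: pd.DataFrame = field(default_factory=pd.DataFrame)
    wgd_pairs: pd.DataFrame = field(default_factory=pd.DataFrame)
    methylation: pd.DataFrame = field(default_factory=pd.DataFrame)

    def to_frame(self) -> pd.DataFrame:
        frames = []
        if len(self.elements):
            df = self.elements.copy()
            df.insert(0, "record_type", "element")
            frames.append(df)
        if len(self.wgd_pairs):
            df = self.wgd_pairs.copy()
            df.insert(0, "record_type", "wgd_pair")
            frames.append(df)
        if len(self.methylation):
            df = self.methylation.copy()
            df.insert(0, "record_type", "methylation")
            frames.append(df)
        return pd.concat(frames, ignore_index=True) if frames else pd.DataFrame()

    def write(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# LTR landscape planting
# ---------------------------------------------------------------------------

_DOMAIN_ORDER = {
    "Ty1_copia": ["GAG", "AP", "INT", "RT", "RH"],
    "Ty3_gypsy": ["GAG", "AP", "RT", "RH", "INT"],
}


def _identity_pct(a: str, b: str) -> float:
    n = min(len(a), len(b))
    same = sum(1 for x, y in zip(a[:n], b[:n]) if x == y)
    return 100.0 * same / n if n else 0.0


def _hit(query, subject, identity, aln_len, q_len, s_start0, s_end0, bit=None):
    """HitRecord with 1-based inclusive subject coordinates from 0-based."""
    return HitRecord(
        query_id=query, subject_id=subject, pct_identity=round(identity, 2),
        aln_length=aln_len, mismatches=int(aln_len * (1 - identity / 100.0)),
        gap_opens=0, q_start=1, q_end=min(aln_len, q_len),
        s_start=s_start0 + 1, s_end=s_end0, e_value=1e-180,
        bit_score=bit if bit is not None else round(2.0 * aln_len * identity / 100.0, 1),
    )


def _draw_age(dist: AgeDistribution, rng: np.random.Generator) -> float:
    if dist.mode == "uniform":
        return float(rng.uniform(dist.t_min, dist.t_max))
    if dist.mode == "burst":
        age = float(rng.normal(dist.burst_time, dist.burst_sd))
        return max(age, 0.0)
    raise ValueError(f"unknown age distribution mode {dist.mode!r}")


@dataclass
class LtrLandscape:
    features: list[FeatureRecord]
    domain_hits: list[DomainHit]
    ltr_hits: list[HitRecord]          # LTR-terminus queries vs genome
    element_hits: list[HitRecord]      # full-element queries vs genome
    query_lengths: dict[str, int]
    element_query_lengths: dict[str, int]
    intact_intervals: dict[str, list[tuple[int, int]]]
    truth_rows: list[dict]
    ltr_pairs: dict[str, tuple[str, str]]   # element id -> (5' LTR, 3' LTR) sequence


class _Cursor:
    """Sequential placement with margins on a set of scaffolds."""

    def __init__(self, genome: Genome, scaffold_ids: Sequence[str],
                 margin: int, rng: np.random.Generator):
        self.genome = genome
        self.ids = list(scaffold_ids)
        self.margin = margin
        self.rng = rng
        self.idx = 0
        self.pos = margin

    def place(self, length: int, spacing: tuple[int, int] = (500, 1500)) -> tuple[str, int]:
        while self.idx < len(self.ids):
            sid = self.ids[self.idx]
            limit = len(self.genome.scaffolds[sid]) - self.margin
            if self.pos + length <= limit:
                start = self.pos
                self.pos += length + int(self.rng.integers(*spacing))
                return sid, start
            self.idx += 1
            self.pos = self.margin
        raise ValueError(
            f"placement overflow: requested {length} bases, no scaffold space left "
            f"(margin {self.margin}, scaffolds {self.ids})"
        )


def _overwrite(genome: Genome, sid: str, start: int, seq: str) -> None:
    s = genome.scaffolds[sid]
    genome.scaffolds[sid] = s[:start] + seq + s[start + len(seq):]


def plant_ltr_landscape(
    genome: Genome,
    ltr_cfg: LtrConfig,
    decoy_cfg: DecoyConfig,
    seed: int | np.random.Generator,
    scaffold_ids: Sequence[str] | None = None,
) -> LtrLandscape:
    """Plant the full element landscape into (a copy region of) the genome.

    Intact elements are LTR + internal + LTR with the five coding domains
    in superfamily order, the two LTRs diverged at d = 2 r T for the
    element's drawn age.  Truncated copies cover 80-100%% of a source
    element at >60%% identity; genuine solos sit far from scaffold ends and
    gaps; each decoy violates exactly one solo filter; non-autonomous
    elements have an LTR pair and internal region but no domain rows.
    Mutates ``genome`` in place and returns all annotations, hit tables and
    truth rows.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    sids = list(scaffold_ids) if scaffold_ids is not None else list(genome.scaffolds)
    margin = 6000
    cursor = _Cursor(genome, sids, margin, rng)
    L = ltr_cfg.ltr_length
    full_len = 2 * L + ltr_cfg.internal_length

    out = LtrLandscape(
        features=[], domain_hits=[], ltr_hits=[], element_hits=[],
        query_lengths={}, element_query_lengths={}, intact_intervals={},
        truth_rows=[], ltr_pairs={},
    )

    def add_truth(eid, status, age, sid, start, end):
        out.truth_rows.append(
            {"id": eid, "status": status, "true_age": age,
             "scaffold_id": sid, "start": start, "end": end}
        )

    intact_seqs: list[tuple[str, str, str]] = []  # (id, full seq, 5' LTR)
    superfamilies = ["Ty1_copia", "Ty3_gypsy"]

    # --- intact and non-autonomous elements --------------------------------
    n_full = ltr_cfg.n_intact + ltr_cfg.n_nonautonomous
    for i in range(n_full):
        autonomous = i < ltr_cfg.n_intact
        eid = f"EL{i:04d}" if autonomous else f"NA{i - ltr_cfg.n_intact:04d}"
        sf = superfamilies[i % 2] if autonomous else "non_autonomous"
        age = _draw_age(ltr_cfg.age_distribution, rng)
        d = 2.0 * ltr_cfg.rate_r * age
        ltr5 = random_sequence(L, 0.40, rng)
        ltr3 = evolve_sequence(ltr5, d, ltr_cfg.kappa, rng)
        internal = random_sequence(ltr_cfg.internal_length, 0.40, rng)
        seq = ltr5 + internal + ltr3
        sid, start = cursor.place(len(seq))
        _overwrite(genome, sid, start, seq)
        end = start + len(seq)
        status = "intact" if autonomous else "non_autonomous"
        out.features.append(FeatureRecord(
            sid, start, end, "+", "LTR_element", eid,
            {"status": status, "superfamily": sf},
        ))
        out.features.append(FeatureRecord(
            sid, start, start + L, "+", "LTR_terminus", f"{eid}_5LTR",
            {"element": eid, "side": "5"},
        ))
        out.features.append(FeatureRecord(
            sid, end - L, end, "+", "LTR_terminus", f"{eid}_3LTR",
            {"element": eid, "side": "3"},
        ))
        out.intact_intervals.setdefault(sid, []).append((start, end))
        out.ltr_pairs[eid] = (ltr5, ltr3)
        add_truth(eid, status, age, sid, start, end)
        if autonomous:
            intact_seqs.append((eid, seq, ltr5))
            # domain rows in superfamily order across the internal region
            dom_w = ltr_cfg.internal_length // 6
            for k, dom in enumerate(_DOMAIN_ORDER[sf]):
                dstart = L + k * dom_w + dom_w // 4
                out.domain_hits.append(
                    DomainHit(eid, dom, dstart, dstart + dom_w // 2, 100.0)
                )
            # the element's own LTRs hit the genome at their own positions
            for qid, (ls, le) in ((f"{eid}_5LTR", (start, start + L)),
                                  (f"{eid}_3LTR", (end - L, end))):
                out.query_lengths[qid] = L
                out.ltr_hits.append(_hit(qid, sid, 100.0, L, L, ls, le))
            out.element_query_lengths[eid] = full_len
            out.element_hits.append(_hit(eid, sid, 100.0, full_len, full_len, start, end))

    if not intact_seqs:
        if ltr_cfg.n_truncated or ltr_cfg.n_solo or decoy_cfg.total:
            raise ValueError("cannot plant solos/truncated without intact elements")
        return out

    # --- truncated loci -----------------------------------------------------
    truncated_spans: list[tuple[str, int, int, str]] = []
    n_trunc = ltr_cfg.n_truncated + decoy_cfg.n_truncated_overlap_solo
    for i in range(n_trunc):
        src_id, src_seq, _ = intact_seqs[i % len(intact_seqs)]
        coverage = float(rng.uniform(0.82, 0.98))
        piece_len = int(coverage * len(src_seq))
        piece = evolve_sequence(src_seq[:piece_len], 0.12, ltr_cfg.kappa, rng)
        sid, start = cursor.place(piece_len)
        _overwrite(genome, sid, start, piece)
        end = start + piece_len
        tid = f"TR{i:04d}"
        identity = _identity_pct(src_seq[:piece_len], piece)
        out.element_hits.append(
            _hit(src_id, sid, identity, piece_len, len(src_seq), start, end)
        )
        out.features.append(FeatureRecord(
            sid, start, end, "+", "TE", tid, {"status": "truncated", "source": src_id}
        ))
        truncated_spans.append((sid, start, end, src_id))
        if i < ltr_cfg.n_truncated:
            add_truth(tid, "truncated", 0.0, sid, start, end)

    # --- genuine solo LTRs ---------------------------------------------------
    def plant_solo(eid: str, status: str, *, sid_start=None, identity_override=None,
                   coverage_override=None, near_gap=False) -> None:
        src_id, _, src_ltr = intact_seqs[rng.integers(0, len(intact_seqs))]
        age = _draw_age(ltr_cfg.age_distribution, rng)
        d = 2.0 * ltr_cfg.rate_r * age
        seq = evolve_sequence(src_ltr, d, ltr_cfg.kappa, rng)
        if sid_start is None:
            sid, start = cursor.place(len(seq))
        else:
            sid, start = sid_start
        _overwrite(genome, sid, start, seq)
        end = start + len(seq)
        if near_gap:
            gap = "N" * 200
            gap_start = end + 100   # strictly inside the 500 bp exclusion zone
            _overwrite(genome, sid, gap_start, gap)
            # keep later cursor placements clear of this gap's exclusion zone
            cursor.pos = max(cursor.pos, gap_start + 200 + 600)
        qid = f"{src_id}_5LTR"
        out.query_lengths.setdefault(qid, L)
        identity = identity_override if identity_override is not None \
            else _identity_pct(src_ltr, seq)
        aln_len = int((coverage_override if coverage_override is not None else 1.0) * L)
        out.ltr_hits.append(
            _hit(qid, sid, identity, aln_len, L, start, start + aln_len)
        )
        out.features.append(FeatureRecord(
            sid, start, end, "+", "TE", eid, {"status": status, "source": src_id}
        ))
        add_truth(eid, status, age, sid, start, end)

    for i in range(ltr_cfg.n_solo):
        plant_solo(f"SO{i:04d}", "solo")

    # --- decoys: each violates exactly one filter ----------------------------
    # (b) scaffold edge: planted < 5 kb from a scaffold start, but clear of
    # the cursor region that begins at the placement margin
    if decoy_cfg.n_edge_solo > len(sids):
        raise ValueError(
            f"placement overflow: {decoy_cfg.n_edge_solo} edge decoys requested, "
            f"only {len(sids)} scaffolds available (one edge slot each)"
        )
    for i in range(decoy_cfg.n_edge_solo):
        plant_solo(f"DE{i:04d}", "decoy_edge", sid_start=(sids[i], 500))
    # (d) gap adjacent
    for i in range(decoy_cfg.n_gap_adjacent_solo):
        plant_solo(f"DG{i:04d}", "decoy_gap", near_gap=True)
    # (c) low coverage and identity
    for i in range(decoy_cfg.n_low_identity_solo):
        plant_solo(f"DL{i:04d}", "decoy_low_identity",
                   identity_override=60.0, coverage_override=0.6)
    # (a) overlap with a truncated locus: hit inside a planted truncated copy
    for i in range(decoy_cfg.n_truncated_overlap_solo):
        sid, tstart, tend, src_id = truncated_spans[ltr_cfg.n_truncated + i]
        qid = f"{src_id}_5LTR"
        out.query_lengths.setdefault(qid, L)
        out.ltr_hits.append(
            _hit(qid, sid, 95.0, L, L, tstart, min(tstart + L, tend))
        )
        out.truth_rows.append(
            {"id": f"DT{i:04d}", "status": "decoy_truncated_overlap",
             "true_age": 0.0, "scaffold_id": sid, "start": tstart,
             "end": min(tstart + L, tend)}
        )

    counts = pd.Series([r["status"] for r in out.truth_rows]).value_counts()
    _LOG.info("planted LTR landscape: %s", counts.to_dict())
    return out


# ---------------------------------------------------------------------------
# Methylome simulation
# ---------------------------------------------------------------------------

def _compartment_of_sites(
    sites: pd.DataFrame,
    features: Sequence[FeatureRecord],
) -> np.ndarray:
    """gene / TE / intergenic label per site; gene wins over TE where both
    apply, everything else is intergenic."""
    labels = np.full(len(sites), "intergenic", dtype=object)
    by_class: dict[str, dict[str, list[tuple[int, int]]]] = {"gene": {}, "TE": {}}
    for rec in features:
        cls = {"gene": "gene", "TE": "TE", "LTR_element": "TE"}.get(rec.feature_class)
        if cls:
            by_class[cls].setdefault(rec.scaffold_id, []).append((rec.start, rec.end))
    for cls in ("TE", "gene"):  # gene assigned second so it wins
        for sid, intervals in by_class[cls].items():
            intervals = sorted(intervals)
            starts = np.array([s for s, _ in intervals])
            ends = np.array([e for _, e in intervals])
            mask = sites["scaffold_id"].to_numpy() == sid
            pos = sites["position"].to_numpy()[mask]
            idx = np.searchsorted(starts, pos, side="right") - 1
            inside = (idx >= 0) & (pos < ends[np.clip(idx, 0, len(ends) - 1)])
            sub = np.nonzero(mask)[0][inside]
            labels[sub] = cls
    return labels


def simulate_methylome(
    genome: Genome,
    features: Sequence[FeatureRecord],
    cfg: MethylomeConfig,
    seed: int | np.random.Generator = 0,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Per-cytosine methylation calls plus a lambda conversion control.

    Site methylation probability is beta-distributed per compartment x
    context; coverage is Poisson; unmethylated reads misread as methylated
    with probability ``conversion_failure``.  Returns (calls, lambda
    control calls, per-site truth with the drawn probability).
    """
    if cfg.coverage_mean <= 0:
        raise ValueError("coverage_mean must be positive")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    sites = scan_cytosines(genome)
    compartments = _compartment_of_sites(sites, features)
    n = len(sites)
    p = np.zeros(n)
    for (comp, ctx), (mean, conc) in cfg.levels.items():
        mask = (compartments == comp) & (sites["context"].to_numpy() == ctx)
        k = int(mask.sum())
        if k:
            p[mask] = rng.beta(mean * conc, (1.0 - mean) * conc, size=k)
    coverage = rng.poisson(cfg.coverage_mean, size=n)
    p_eff = p + (1.0 - p) * cfg.conversion_failure
    meth = rng.binomial(coverage, p_eff)
    calls = sites.copy()
    calls["count_methylated"] = meth
    calls["count_unmethylated"] = coverage - meth
    truth = sites[["scaffold_id", "position", "strand", "context"]].copy()
    truth["compartment"] = compartments
    truth["p_true"] = p

    # lambda-like spike-in: fully unmethylated control of the classic length
    lam_genome = Genome({"lambda_control": random_sequence(
        cfg.lambda_length, 0.50, rng)})
    lam_sites = scan_cytosines(lam_genome)
    lam_cov = rng.poisson(cfg.coverage_mean, size=len(lam_sites))
    lam_meth = rng.binomial(lam_cov, cfg.conversion_failure)
    lam = lam_sites.copy()
    lam["count_methylated"] = lam_meth
    lam["count_unmethylated"] = lam_cov - lam_meth
    cols = ["scaffold_id", "position", "strand", "count_methylated",
            "count_unmethylated", "context", "trinucleotide"]
    return calls[cols], lam[cols], truth


def apply_deamination(
    genome: Genome,
    methylome_truth: pd.DataFrame,
    deamination_rate: float,
    seed: int | np.random.Generator = 0,
) -> Genome:
    """Convert methylated cytosines toward thymine.

    Each cytosine with truth methylation probability p becomes T (G -> A
    for minus-strand cytosines) with probability rate * p; unmethylated
    sites are untouched.  Returns a new Genome.
    """
    if not 0.0 <= deamination_rate <= 1.0:
        raise ValueError(f"deamination rate {deamination_rate} outside [0, 1]")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    out = Genome(dict(genome.scaffolds))
    if deamination_rate == 0.0 or methylome_truth.empty:
        return out
    for sid, sub in methylome_truth.groupby("scaffold_id"):
        arr = bytearray(out.scaffolds[sid], "ascii")
        hit = rng.random(len(sub)) < deamination_rate * sub["p_true"].to_numpy()
        for pos, strand in zip(
            sub["position"].to_numpy()[hit], sub["strand"].to_numpy()[hit]
        ):
            arr[pos] = ord("T") if strand == "+" else ord("A")
        out.scaffolds[sid] = arr.decode("ascii")
    return out


# ---------------------------------------------------------------------------
# Scenario composition
# ---------------------------------------------------------------------------

@dataclass
class GenomeBundle:
    config: ScenarioConfig
    genome: Genome
    outgroup: Genome
    features: list[FeatureRecord]
    outgroup_features: list[FeatureRecord]
    gaps: GapRegistry
    truth: TruthTable
    hits_self: list[HitRecord]
    hits_cross: list[HitRecord]
    landscape: LtrLandscape
    methylome: pd.DataFrame
    lambda_control: pd.DataFrame
    methylome_truth: pd.DataFrame

    def cds_of(self, gene_id: str) -> str:
        rec = next(f for f in self.features + self.outgroup_features
                   if f.id == gene_id and f.feature_class == "gene")
        source = self.genome if any(
            f.id == gene_id for f in self.features if f.feature_class == "gene"
        ) else self.outgroup
        return source.scaffolds[rec.scaffold_id][rec.start:rec.end]

    def write(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_fasta(self.genome, out / "genome.fasta")
        write_fasta(self.outgroup, out / "outgroup.fasta")
        write_gff3(self.features, out / "annotations.gff3")
        write_gff3(self.outgroup_features, out / "outgroup.gff3")
        self.truth.write(out / "truth.tsv")
        write_hit_table(self.hits_self, out / "hits.self.tsv")
        write_hit_table(self.hits_cross, out / "hits.cross.tsv")
        write_hit_table(self.landscape.ltr_hits, out / "hits.ltr.tsv")
        write_hit_table(self.landscape.element_hits, out / "hits.element.tsv")
        pd.DataFrame(
            [
                {"element_id": d.element_id, "domain": d.domain,
                 "start": d.start, "end": d.end, "score": d.score}
                for d in self.landscape.domain_hits
            ]
        ).to_csv(out / "domains.tsv", sep="\t", index=False)
        write_cx_report(self.methylome, out / "methylome.cx.tsv")
        write_cx_report(self.lambda_control, out / "lambda.cx.tsv")
        write_config(self.config.to_flat(), out / "scenario.config")


def _plant_gene_blocks(
    genome: Genome,
    scaffold_pool: list[str],
    cds_list: Sequence[str],
    ids: Sequence[str],
    block_size: int,
    rng: np.random.Generator,
    shuffle_block_idx: set[int] | None = None,
    spacer_genes: int = 20,
    filler_prefix: str = "fil",
) -> list[FeatureRecord]:
    """Plant CDS blocks consecutively; returns gene features.

    Blocks never straddle scaffolds; block order and in-block gene order
    follow the input unless a block index is marked for shuffling.  Between
    blocks, ``spacer_genes`` filler genes without homologs separate the
    blocks in gene-rank space, so adjacent blocks cannot merge into one
    chained segment.
    """
    features: list[FeatureRecord] = []
    margin = 2000
    pool = list(scaffold_pool)
    if not pool:
        raise ValueError("placement overflow: no scaffolds available for genes")
    sidx, pos = 0, margin
    n_blocks = math.ceil(len(cds_list) / block_size)
    filler_count = 0
    for b in range(n_blocks):
        lo, hi = b * block_size, min((b + 1) * block_size, len(cds_list))
        idx = list(range(lo, hi))
        if shuffle_block_idx and b in shuffle_block_idx:
            idx = [idx[i] for i in rng.permutation(len(idx))]
        block_span = (
            sum(len(cds_list[i]) for i in idx) + (hi - lo) * 900
            + spacer_genes * (450 + 900)
        )
        sid = pool[sidx]
        if pos + block_span > len(genome.scaffolds[sid]) - margin:
            sidx += 1
            pos = margin
            if sidx >= len(pool):
                raise ValueError(
                    f"placement overflow: gene block of {block_span} bases, "
                    f"no scaffold space left in {pool}"
                )
            sid = pool[sidx]
        for i in idx:
            cds = cds_list[i]
            _overwrite(genome, sid, pos, cds)
            features.append(FeatureRecord(
                sid, pos, pos + len(cds), "+", "gene", ids[i], {"block": str(b)}
            ))
            pos += len(cds) + int(rng.integers(400, 800))
        for _ in range(spacer_genes):
            filler = random_cds(150, rng)
            _overwrite(genome, sid, pos, filler)
            features.append(FeatureRecord(
                sid, pos, pos + len(filler), "+", "gene",
                f"{filler_prefix}{filler_count:04d}", {"block": "-"},
            ))
            filler_count += 1
            pos += len(filler) + int(rng.integers(400, 800))
    return features


def generate_scenario(config: ScenarioConfig) -> GenomeBundle:
    """Generate the full scenario bundle (in memory; ``bundle.write`` emits
    the file set).  Deterministic: a fixed config yields an identical bundle."""
    seed = config.seed
    rng_bg = stage_rng(seed, "background")
    genome = Genome({
        f"s{i + 1:02d}": random_sequence(config.scaffold_length, config.gc_target, rng_bg)
        for i in range(config.n_scaffolds)
    })

    # --- WGD paranome -------------------------------------------------------
    wgd = config.wgd
    rng_wgd = stage_rng(seed, "wgd")
    n_pairs = wgd.n_retained_pairs
    ancestral = [random_cds(wgd.cds_codons, rng_wgd) for _ in range(n_pairs)]
    pairs, realized = simulate_wgd_paralogs(
        ancestral, wgd.ks_mean, wgd.ks_sd, n_pairs, rng_wgd
    )
    ids_a = [f"gA{i:04d}" for i in range(n_pairs)]
    ids_b = [f"gB{i:04d}" for i in range(n_pairs)]
    n_blocks = math.ceil(n_pairs / wgd.block_size) if n_pairs else 0
    n_shuffled = int(round(wgd.shuffle_fraction * n_blocks))
    shuffled = set(
        rng_wgd.choice(n_blocks, size=n_shuffled, replace=False)
    ) if n_shuffled else set()

    # A copies, then B copies on later scaffolds (duplicates on distinct
    # scaffolds); gene scaffolds are taken from the front of the pool
    genes_per_scaffold_span = (
        wgd.block_size * (3 * wgd.cds_codons + 900) + 20 * (450 + 900) + 4000
    )
    blocks_per_scaffold = max(1, (config.scaffold_length - 4000) // genes_per_scaffold_span)
    n_gene_scaffolds = 2 * max(1, math.ceil(n_blocks / blocks_per_scaffold)) if n_pairs else 0
    all_sids = list(genome.scaffolds)
    gene_sids_a = all_sids[: n_gene_scaffolds // 2]
    gene_sids_b = all_sids[n_gene_scaffolds // 2: n_gene_scaffolds]
    te_sids = all_sids[n_gene_scaffolds:]
    features: list[FeatureRecord] = []
    if n_pairs:
        features += _plant_gene_blocks(
            genome, gene_sids_a, [a for a, _ in pairs], ids_a,
            wgd.block_size, rng_wgd, filler_prefix="filA",
        )
        features += _plant_gene_blocks(
            genome, gene_sids_b, [b for _, b in pairs], ids_b,
            wgd.block_size, rng_wgd, shuffle_block_idx=shuffled,
            filler_prefix="filB",
        )

    # paranome self-hit table: one row per planted pair (both directions),
    # plus weak noise rows that the e-value cutoff must remove
    hits_self: list[HitRecord] = []
    for ga, gb, (ca, _cb) in zip(ids_a, ids_b, pairs):
        length = len(ca)
        hits_self.append(_hit(ga, gb, 92.0, length, length, 0, length, bit=500.0))
        hits_self.append(_hit(gb, ga, 92.0, length, length, 0, length, bit=500.0))
    rng_noise = stage_rng(seed, "noise_hits")
    all_gene_ids = ids_a + ids_b
    for _ in range(wgd.n_noise_hits if n_pairs else 0):
        qa, qb = rng_noise.choice(len(all_gene_ids), size=2, replace=False)
        rec = _hit(all_gene_ids[qa], all_gene_ids[qb], 40.0, 120, 600, 0, 120, bit=45.0)
        rec.e_value = 1e-6   # above the 1e-10 family cutoff by design
        hits_self.append(rec)

    # --- outgroup (no WGD): single-copy blocks ------------------------------
    rng_og = stage_rng(seed, "outgroup")
    outgroup = Genome({
        f"og{i + 1:02d}": random_sequence(
            config.scaffold_length, config.gc_target, rng_og
        )
        for i in range(max(1, n_gene_scaffolds // 2 or 1))
    })
    og_ids = [f"og{i:04d}" for i in range(n_pairs)]
    og_cds = [
        evolve_sequence(a, wgd.outgroup_divergence, config.ltr.kappa, rng_og)
        for a, _ in pairs
    ]
    outgroup_features = _plant_gene_blocks(
        outgroup, list(outgroup.scaffolds), og_cds, og_ids, wgd.block_size,
        rng_og, filler_prefix="filO",
    ) if n_pairs else []
    hits_cross: list[HitRecord] = []
    for og, ga, gb, (ca, _) in zip(og_ids, ids_a, ids_b, pairs):
        length = len(ca)
        for main in (ga, gb):
            hits_cross.append(_hit(og, main, 90.0, length, length, 0, length, bit=480.0))
            hits_cross.append(_hit(main, og, 90.0, length, length, 0, length, bit=480.0))

    # --- LTR landscape ------------------------------------------------------
    rng_ltr = stage_rng(seed, "ltr")
    landscape = plant_ltr_landscape(
        genome, config.ltr, config.decoys, rng_ltr, scaffold_ids=te_sids
    )
    features += landscape.features

    # --- gaps (from the planted N runs) -------------------------------------
    gaps = find_assembly_gaps(genome, min_run=10)

    # --- methylome ----------------------------------------------------------
    rng_meth = stage_rng(seed, "methylome")
    if config.deamination_rate > 0:
        # provisional truth draw drives deamination; the methylome is then
        # simulated on the eroded genome
        _, _, pre_truth = simulate_methylome(
            genome, features, config.methylome, stage_rng(seed, "deamination_truth")
        )
        genome = apply_deamination(
            genome, pre_truth, config.deamination_rate, stage_rng(seed, "deamination")
        )
    methylome, lambda_control, methylome_truth = simulate_methylome(
        genome, features, config.methylome, rng_meth
    )

    # --- truth table --------------------------------------------------------
    truth = TruthTable(
        elements=pd.DataFrame(landscape.truth_rows),
        wgd_pairs=pd.DataFrame(
            {"id": ids_a, "partner_id": ids_b, "true_ks": realized}
        ) if n_pairs else pd.DataFrame(),
        methylation=pd.DataFrame(
            [
                {"compartment": comp, "context": ctx, "beta_mean": mean,
                 "beta_concentration": conc}
                for (comp, ctx), (mean, conc) in config.methylome.levels.items()
            ]
        ),
    )
    _LOG.info(
        "scenario: %d scaffolds, %d genes, %d planted elements, %d cytosine calls",
        len(genome.scaffolds), 2 * n_pairs, len(landscape.truth_rows), len(methylome),
    )
    return GenomeBundle(
        config=config, genome=genome, outgroup=outgroup,
        features=features, outgroup_features=outgroup_features,
        gaps=gaps, truth=truth, hits_self=hits_self, hits_cross=hits_cross,
        landscape=landscape, methylome=methylome,
        lambda_control=lambda_control, methylome_truth=methylome_truth,
    )
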