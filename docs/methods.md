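# Methods

This note documents the models behind each module, the parameters that
matter, the numerical choices, and what the synthetic scenarios do and do
not establish about real data.

## LTR insertion dating

**Model.** At insertion a retrotransposon's 5′ and 3′ LTRs are identical;
they then diverge independently under the host's neutral substitution
process. The age estimate is T = K/(2r), with K the Kimura two-parameter
(K2P) distance between the aligned LTRs and r the per-site per-year
substitution rate. The factor 2 counts both LTR lineages.

**Alignment.** LTR pairs are aligned by affine-gap global dynamic
programming (Gotoh recurrence; match 5, mismatch −4, gap open −10, gap
extend −1, all configurable), with a deterministic tie-break (diagonal,
then up, then left) so that results are reproducible. The DP kernel is
JIT-compiled; a brute-force pure-Python DP serves as the test oracle. A
dedicated pairwise aligner was preferred over a general multiple aligner
because pairwise global alignment is exactly the sub-problem, and a
self-contained DP can be verified exhaustively.

**K2P.** P and Q are transition and transversion proportions over
ungapped, non-ambiguous columns; K = −½·ln((1−2P−Q)·√(1−2Q)). When the
logarithm's argument is non-positive the element is flagged undatable
(saturated) and reported in its own category rather than silently
clamped; undatable elements are excluded from age histograms.

**Rates.** Default r = 2.2 × 10⁻⁹ substitutions/site/year (a slow
gymnosperm-scale clock); 1.8 × 10⁻⁸ is provided as a named config key for
fast-clock angiosperm lineages. Ages are stored in years; the reporting
layer converts to My.

**Accuracy.** For a 5-kb LTR at d = 2rT ∈ [0.002, 0.009] the binomial
sampling noise of the substitution count alone gives a per-element
relative standard deviation of roughly √(1/(n·d)) ≈ 12–30%; no unbiased
estimator can beat this at that sequence length. The recovery metric used
in the tests is therefore the **signed relative error averaged over
elements** — a calibration (bias) measure, which the pipeline keeps near
zero — not the mean absolute error, which is dominated by irreducible
per-element noise.

## Element classification and the solo-LTR filters

Superfamily is a function of the element-local order of coding domains:
ENV anywhere → Retroviridae; core order INT–RT–RH or RH–RT–INT →
Ty1-copia; RT–RH–INT or INT–RH–RT → Ty3-gypsy; any other non-empty subset
of the core → incomplete; no domains → non-autonomous. "RH" and "RNaseH"
are one token. Intactness requires the full set {GAG, AP, INT, RT, RH}.
Reverse-transcriptase segments for phylogenies must exceed 140 aa with at
most one stop codon; the longest survivor per element is kept.

Solo-LTR detection takes LTR-terminus-vs-genome hits (both the 5′ and 3′
LTR of every intact element are used as queries; overlapping genomic hits
are deduplicated keeping the highest bit score). Candidates not
overlapping an annotated intact element are filtered, in order:
(a) overlap with a truncated locus, (b) distance to a scaffold end
strictly below 5,000 bp, (c) coverage < 0.7 **or** identity < 0.7,
(d) distance to an assembly-gap N-run strictly below 500 bp. Coverage is
aligned query length over query length; identity is the hit's percent
identity. Threshold inequalities are strict, as published. Rejections are
counted per rule so accounting tables can be reproduced from logs. The
solo:intact ratio is reported to two decimals, rounding half away from
zero.

## Ks distributions and WGD peaks

**Ks estimator.** Nei–Gojobori (1986): per-codon synonymous site
fractions averaged over both sequences (changes creating stop codons
count as nonsynonymous); observed differences averaged over equal-weight
minimal mutational pathways, excluding pathways through stop codons (if
every pathway is blocked, all are used with stop steps counted
nonsynonymous); Jukes–Cantor correction d = −¾·ln(1 − 4p/3) applied to
both proportions, with p ≥ ¾ raising a saturation error. NG86 was chosen
over ML codon models because it is closed-form, fast at desk scale, and
verifiable against an independent implementation; the estimator is
pluggable should an ML backend be wanted.

**Families and weighting.** Families are connected components of the hit
graph after discarding edges with E-value above 10⁻¹⁰ (a dense Markov
clustering implementation — column-normalized expansion/inflation
iteration, default inflation 1.5 — is available as `method="markov"`).
Families are subdivided into subfamilies by connectivity at Ks ≤ 5;
saturated pairs count as exceeding the threshold and still force splits.
Each subfamily gets a neighbor-joining tree on the Ks matrix (saturated
entries capped at 10); NJ is deterministic (lowest-index tie-break) and
rooted at the last join, giving exactly n−1 duplication nodes for n
leaves. Each node's m cross-clade pairs carry weight 1/m, so weights per
subfamily sum to n−1 exactly. Only the duplication-node partition matters
for weighting, which is why a fast distance method suffices where a
likelihood tree builder was originally used.

**Peaks.** Weighted Gaussian KDE over Ks in (0.05, 5] — the floor
excludes the allelic/recent-duplicate spike, where peak finding is
meaningless — with Silverman bandwidth on the weighted sample
(fixed-bandwidth override available). Peaks are local maxima above 10% of
the global density maximum. Confidence intervals are percentiles (90% by
default) of matched peak locations over 200 weighted bootstrap resamples.
The KDE bandwidth and bootstrap count are implementation defaults; the
original study does not print them. The absolute-dating selection window
0.7 ≤ Ks ≤ 1.25 is inclusive on both ends (inclusivity was unstated;
configurable).

## Collinearity and synteny

Hits are filtered by c-score: kept iff bit score ≥ 0.5 × the best bit
score of the same query (the per-query convention; a symmetric
max(query-best, subject-best) mode exists). Tandem arrays — same-scaffold
homologs within 5 ranks — collapse to their lowest-rank representative
before chaining. Collinear segments are maximal anchor chains strictly
monotone in both genomes' gene ranks (same or inverted orientation), with
consecutive-anchor gaps ≤ 15 genes, admitted at ≥ 5 anchors; the chaining
is a deterministic greedy sweep in the rank–rank dot plot rather than a
statistical cluster test, with min-anchors plus max-gap as the admission
rule. Syntenic (order-free) segments are transitive clusters of anchors
within 15 ranks of each other in both genomes, admitted at ≥ 5 shared
homologs; clusters containing a collinear chain are labeled collinear, so
syntenic detections always include collinear ones. Multiplicon ratios
merge overlapping reference-side intervals and count pairwise-disjoint
query-side intervals covering them; ratio 2 is the one-to-two pattern
expected under a query-lineage WGD. Only pairwise (level-2) segments are
produced.

## Methylome statistics

Contexts are read strand-locally: C followed by G → CG; C-H-G → CHG;
C-H-H → CHH (H ∈ {A,T,C}); minus-strand cytosines are genomic Gs read
upstream in reverse complement. Windows truncated by a scaffold end or
containing N are uncallable. Site level is n_meth/n_total; aggregate
levels are read-weighted (Σm/Σ(m+u)) by default, matching the per-site
ratio definition and robust at low coverage — a site-averaged mode exists
behind a flag. Conversion efficiency is 1 minus the apparent methylation
of a fully unmethylated spike-in control. Level correction by the
conversion failure is off by default; the efficiency is reported
alongside.

**DMRs.** Candidates are maximal runs of ≥ 5 consecutive shared sites
(spacing ≤ 300 bp) whose per-site differences share a sign and whose mean
|difference| exceeds 0.1 — the one normative rule. Each candidate is
scored by the rank-sum statistic on per-site levels. Because candidates
are selected on the same data they are tested on, naive rank-sum
p-values are badly anti-conservative (in null simulations ~23% of
replicates produced a spurious q < 0.05 call); significance is therefore
calibrated against a permutation null: per-site group labels are flipped
at random, the segmentation re-run, and the best candidate statistic
recorded per permutation (0 if none). A candidate's p-value is the
fraction of permutations whose best statistic matches or beats it. This
max-statistic null is already familywise-adjusted across candidates, so
no further multiple-testing correction is stacked on top. With 100
permutations the smallest attainable p is 1/101 ≈ 0.0099. Under a
same-parameters null the false-call rate per tested candidate region
measures ~0.003, and a planted 0.7-difference region is recovered at
q ≈ 0.01.

**Compartments.** Intergenic is the complement of gene spans; TEs are a
separate overlay, so a region can be 100% intergenic and 100% TE at once
— matching how TE and intergenic proportions are reported separately.
Compartment GC is (G+C)/(A+C+G+T) with N excluded from both numerator and
denominator.

## The synthetic-data generator

One root seed; every stage (background sequence, WGD, outgroup, LTR
landscape, methylome, deamination) draws from an independent substream
keyed by the stage name, so adding stages never perturbs earlier stages'
draws, and a fixed config regenerates a byte-identical bundle.

**Substitution process.** Two-parameter, site-independent, with
transition bias κ (default 2.0). For target divergence d the exact
per-site transition and transversion probabilities are
P = ¼ + ¼e^{−4βt} − ½e^{−2(α+β)t} and Q = ½(1 − e^{−4βt}) with
βt = d/(κ+2), αt = κβt, so the K2P estimator applied to the simulated
pair recovers d in expectation. No indels are simulated in LTR pairs by
default: indel simulation would conflate alignment quality with dating
accuracy.

**WGD.** Each retained pair's target Ks is lognormal with arithmetic
mean `ks_mean` (preset 1.0 — the depth of the duplicate-gene signature
peak the analyses are built to detect) and sd 0.15. The duplicate
accumulates single-base substitutions chosen only among changes
synonymous for the current codon, until the realized NG86 Ks (maintained
incrementally per codon) reaches the draw; the realized value is recorded
as truth, and targets that cannot be reached before synonymous saturation
raise an error naming the pair. Duplicates are planted as collinear
blocks of 25 genes on scaffolds distinct from their partners, separated
by 20 non-homologous filler genes so that adjacent blocks are
distinguishable in rank space; an optional `shuffle_fraction` permutes
gene order inside a fraction of duplicate blocks to emulate post-WGD
rearrangement and exercise the synteny-vs-collinearity distinction. A
non-WGD outgroup genome carries single-copy versions of every block
(nucleotide divergence 0.05), giving 2:1 multiplicon ratios a ground
truth.

**LTR landscape.** Intact elements are LTR + internal + LTR (preset 5 kb
each) with domain rows in superfamily order; the 3′ LTR is the 5′ LTR
evolved at d = 2r·age. Ages come from a uniform window or a Gaussian
burst (preset: burst at 1.5 Mya, sd 0.4 My — a recent activity burst
within the last two million years, under r = 2.2 × 10⁻⁹). Truncated
copies cover 82–98% of a source element at ~89% identity; solos are
single evolved LTR copies placed ≥ 6 kb from scaffold ends and clear of
gaps. Four decoy classes violate exactly one filter each: an edge decoy
sits < 5 kb from a scaffold start; a gap decoy gets a 200-bp N-run
planted 100 bp downstream; a low-identity decoy's hit row carries
coverage 0.6 and identity 60%; a truncated-overlap decoy is an LTR hit
inside a planted truncated locus. Because detection consumes hit tables,
the generator emits the tables a search tool would produce, with
identities measured from the actually planted sequences.

**Methylome.** Per-site methylation probability is Beta-distributed per
compartment × context (preset means: TE 0.90/0.80/0.40 and intergenic
0.80/0.75/0.35 for CG/CHG/CHH, genes lower — a heavily methylated
gymnosperm-like profile with unusually high CHH); coverage is
Poisson(20); unmethylated reads misread as methylated with probability
0.005 (the conversion failure); the lambda-like control is a generated
48,502-base random sequence — only its unmethylated status matters, so
the real phage sequence is not used. Deamination converts each cytosine
C→T (G→A on the minus strand) with probability rate × its truth
methylation probability; when enabled in a scenario, a provisional truth
draw drives the erosion and the read-level methylome is then simulated on
the eroded genome.

**Scale.** The preset genome is 12 × 400 kb = 4.8 Mb with 200 retained
duplicate pairs, 60 intact / 100 solo / 20 truncated / 20 non-autonomous
elements and 5 decoys per class; it generates in ~10 s and the full
peak-recovery pipeline runs in ~15 s on one CPU. These sizes were chosen
so every recovery check rests on enough replication (≥ 50 dated elements,
≥ 1,000 sites per methylation cell, 8 duplicate blocks) while the whole
suite stays interactive.

## What passing tests show — and what they do not

The scenarios plant exactly the signals the methods assume: independent
sites, no indels in LTR pairs, clean annotation, hit tables free of
spurious homology beyond configured noise rows, compartments that
partition the genome. Passing recovery tests therefore demonstrates that
the estimators are correctly implemented and calibrated under their own
model assumptions — unbiased dating, exact weight conservation, exact
filter semantics, level recovery within binomial noise. They do not
demonstrate robustness to real-data pathologies: nested or recombined
elements, segmental duplications mimicking WGD peaks, alignment error in
diverged LTRs, bisulfite mapping bias, or annotation noise. Genome-scale
observed quantities from the motivating system (repeat fraction, global
GC, absolute WGD age) require the full multi-gigabase assembly and
fossil-calibrated dating and are out of scope; the property-based checks
above are the desk-scale counterpart.

## Known limitations

- The greedy anchor chainer can fragment a block whose anchors alternate
  orientations; it has no cluster-significance test.
- Markov clustering runs on a dense matrix; it is meant for desk-scale
  graphs, not proteome-scale ones.
- The DMR caller tests two pooled samples (one per group); replicated
  designs would permute whole samples instead of site labels.
- NG86 saturates near Ks ≈ 3–4; deeper divergences are reported as
  saturated rather than estimated.
- The simulator plants elements on the plus strand only; strandedness of
  elements is not exercised.
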