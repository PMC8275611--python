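# wgd_preset: the default ground-truth scenario.
#
# Encodes the inferred genome history this package is built to detect:
#   * one ancient whole-genome duplication whose retained duplicate pairs
#     have a synonymous divergence (Ks) depth centered at 1.0 -- the
#     signature peak a paranome Ks age distribution should recover;
#   * a recent burst of LTR-retrotransposon activity centered at 1.5
#     million years ago (within the last 1-2 My) under a substitution
#     clock of 2.2e-9 substitutions/site/year;
#   * a heavily methylated, GC-poor genome in which transposable-element
#     and intergenic compartments carry high CG/CHG methylation and
#     unusually high CHH methylation;
#   * decoy solo-LTR candidates that each violate exactly one of the four
#     detection filters (scaffold edge, assembly gap, coverage/identity,
#     truncated-element overlap).

seed = 1
n_scaffolds = 12
scaffold_length = 400000
gc_target = 0.35
deamination_rate = 0.0

wgd.ks_mean = 1.0
wgd.ks_sd = 0.15
wgd.n_retained_pairs = 200
wgd.block_size = 25
wgd.n_blocks = 8
wgd.cds_codons = 200
wgd.shuffle_fraction = 0.0
wgd.n_noise_hits = 20
wgd.outgroup_divergence = 0.05

ltr.n_intact = 60
ltr.n_truncated = 20
ltr.n_solo = 100
ltr.n_nonautonomous = 20
ltr.ltr_length = 5000
ltr.internal_length = 5000
ltr.rate_r = 2.2e-9
ltr.kappa = 2.0
ltr.age.mode = burst
ltr.age.t_min = 500000
ltr.age.t_max = 2000000
ltr.age.burst_time = 1500000
ltr.age.burst_sd = 400000

decoys.n_edge_solo = 5
decoys.n_gap_adjacent_solo = 5
decoys.n_low_identity_solo = 5
decoys.n_truncated_overlap_solo = 5

methylome.gene.CG.mean = 0.60
methylome.gene.CHG.mean = 0.40
methylome.gene.CHH.mean = 0.15
methylome.TE.CG.mean = 0.90
methylome.TE.CHG.mean = 0.80
methylome.TE.CHH.mean = 0.40
methylome.intergenic.CG.mean = 0.80
methylome.intergenic.CHG.mean = 0.75
methylome.intergenic.CHH.mean = 0.35
methylome.coverage_mean = 20.0
methylome.conversion_failure = 0.005
methylome.lambda_length = 48502
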