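# Methods

This note records the models the package implements, the assumptions they
make, the defaults and why, and the numerical conventions a maintainer would
need to change any of them safely.

## Site and genotype masking

The filter stage treats the VCF's per-site INFO annotations as given (they
come from the upstream caller) and applies seven rules. Rules 1–4 and 6–7
mask whole sites; rule 5 masks individual genotypes:

1. MQ0 fraction > `mq0_max` (default 0.10);
2. RMS mapping quality < `mq_min` (default 50);
3. strand mapping-quality difference, p < `strand_p_max` (default 0.001);
4. summed depth over samples outside the dataset-wide
   [`depth_lo_pct`, `depth_hi_pct`] percentiles (defaults 2.5, 97.5);
5. heterozygous genotypes whose (ref, alt) allele depths fail an exact
   binomial balance test at PHRED > `ab_phred_max` (default 20) are set to
   missing;
6. inbreeding coefficient F < `inbreeding_min` (default −0.2);
7. missing-genotype fraction > `missing_max` (default 0.20), evaluated
   after rule 5.

Design choices:

* **Strand test.** Per-read mapping qualities are not available in a VCF, so
  the strand rule is a two-sided two-sample z-test on per-strand
  (mean, sd, n) summaries carried in INFO (keys `MQSF`/`MQSR`). The statistic
  is isolated in `strand_mq_pvalue` so an alternative test can be swapped in.
* **Excess-heterozygosity direction.** The rule exists to remove collapsed
  paralogs and cross-contamination, which inflate heterozygosity and drive F
  strongly negative. The default floor is therefore −0.2: sites with
  F < −0.2 are masked. A positive threshold of the same magnitude would mask
  nearly every polymorphic site and would not target excess heterozygosity.
* **Monomorphic sites.** When one allele is absent, H_exp = 0 and F carries
  no information; F is defined as 0 and rule 6 never fires.
* **Depth percentiles** are computed once, over all input sites, before any
  masking — they are a property of the dataset, not of the surviving sites.
* **Ordering.** Every site rule is a pure predicate on the input
  annotations, so the retained set is independent of application order; only
  rule 7 is defined relative to rule 5 (missingness counts the
  allele-balance-masked genotypes). Masking is idempotent.
* Genotypes without an AD field skip rule 5 and are counted in the report.

Coordinates are VCF 1-based; windows are 0-based half-open `[wS, (w+1)S)`,
so position p belongs to window `(p−1)//S`. Default window size S = 100 kb.

## Windowed distances and the net correction

For unphased diploid genotype codes (alt-allele counts) the expected
per-site mismatch is `d(gᵢ,gⱼ) = (gᵢ(2−gⱼ) + gⱼ(2−gᵢ))/4`, the mean over
the four haplotype pairings — identically the mean over the two possible
phase alignments, so the formula agrees exactly with phase-aware averaging
on fully phased data (this is an asserted oracle equivalence, not an
approximation).

Per window, the package accumulates the summed mismatches and a per-pair
denominator: the window's accessible-base count minus the sites missing in
either member of the pair (unbiased per-pair rates under missingness).
Genome-wide distances are ratios of sums over windows — never means of
per-window ratios — which makes them invariant to how sites are windowed.
Windows with a zero pair denominator contribute nothing.

The split-tree ("net", Nei's d_a) distance subtracts the mean of the pair's
two within-individual heterozygosities. Pairwise (not global) averaging is
used because it gives E[net] = 0 for two members of one panmictic
population, which is the property the split tree and the dating step rely
on. Sampling noise can make net entries slightly negative; they are kept in
the output matrices and clamped to 0 only when a matrix is fed to
neighbour joining (negative inputs distort NJ's Q criterion).

## Tree inference and support

Neighbour joining is standard Saitou–Nei with two pinned conventions:
Q-matrix ties break on the lowest (row, column) pair, and negative branch
estimates are clamped to zero with the deficit moved to the sister branch so
the joined pair's summed length is preserved. NJ is consistent on additive
matrices (verified against exhaustive path-length oracles) and is a
consistent species-tree estimator under incomplete lineage sorting, which is
why it is used on the genome-wide matrix. Outgroup rooting inserts the root
at the midpoint of the outgroup's pendant edge and preserves all leaf-to-leaf
path lengths; re-rooting is idempotent.

Block-bootstrap support resamples whole windows (the exchangeable blocks)
with replacement, re-sums difference and denominator counts, re-forms the
per-bp matrix — re-deriving the heterozygosity correction from the resampled
windows when net mode is on — and rebuilds the tree per replicate.
Resampling counts rather than per-window ratio matrices keeps denominators
honest under missingness. One seeded generator drives all replicates in
sequence; a replicate with a zero denominator for any pair is rejected,
logged and redrawn. Support is the percentage of replicates whose tree
contains the query bipartition (either side).

Local gene-tree support builds one NJ tree per window from that window's
per-bp matrix, by default restricted to the two groups' samples (the
outgroup would otherwise vote on splits it is not part of; a flag includes
all leaves). The supporting fraction over evaluable windows is the ILS
summary: it falls toward zero as the split becomes young relative to Ne.

## Split-time dating

The split node is the MRCA of the two groups in the rooted net tree (an
error is raised if it does not separate them). Its height h — the mean
tip-to-node path length, in per-bp distance units — accumulates μ per
generation per lineage, so `t = g·h/μ` years with generation time g.
Defaults: μ = 3.5×10⁻⁹ per bp per generation with confidence interval
1.6–4.7×10⁻⁹ (the Lake Malawi cichlid rate), g = 3 years. Rate uncertainty
propagates inversely: bounds `t·μ/μ_high` and `t·μ/μ_low`. The estimator
assumes constant population sizes and mutation rate; the net correction
removes the expected ancestral-coalescence offset (≈ 2Ne generations, i.e.
≈ 2Ne·g years of upward bias if omitted) but no demographic model is
fitted, and the only uncertainty propagated is the mutation rate, by
design. Machine outputs keep full precision; human-readable output rounds
to the nearest 1 ka.

## Geometric morphometrics

TPS records (`LM=k`, k coordinate lines, optional `ID`/`IMAGE`/`SCALE`) are
parsed with coordinates multiplied by the scale factor on load (missing
scale = 1). Centroid size is the root summed squared landmark deviation
from the centroid, computed before alignment.

GPA centres each configuration, scales it to unit centroid size (full
Procrustes), and iteratively rotates each to the current mean, renormalising
the mean each pass; convergence is a summed squared mean change < 1e-10
(cap 100 iterations, flagged). Rotations come from the SVD of the
cross-covariance with a determinant correction — reflections are never
used, matching standard geometric-morphometric practice. Because a GPA
solution is only defined up to a common rotation, the output is put in a
canonical frame: the mean shape's principal axes are aligned with the
coordinate axes and the largest-magnitude mean coordinate is made positive.
This makes the aligned coordinates invariant (to 1e-9) to similarity
transforms applied to any input and to input order. Tangent-space
projection is implemented but off by default: for congeneric fish the shape
variation is small enough that curved and tangent coordinates differ
negligibly; the flag documents the deviation knob.

Shape PCA eigen-decomposes the covariance matrix of the flattened 2k-vector
of Procrustes coordinates; scores are centred projections, percent variance
is eigenvalue share, and each loading vector is oriented so its
largest-magnitude entry is positive. Four eigenvalues are numerically zero
by construction (the similarity degrees of freedom removed by GPA). The
downstream group statistics (ANOVA of scores, allometry regressions) are
deliberately out of scope: scores and centroid sizes are exported for any
statistics package.

## Synthetic data

The genotype simulator is a continuous-time structured coalescent:
within each population, k lineages coalesce at rate k(k−1)/2 per 2Ne
generations (exponential waiting times); populations A and B merge into an
ancestral population at `t_split` and the outgroup lineage pool joins at
`t_outgroup`. The ancestral size equals Ne by default so the net-divergence
identity E[net] = 2μT holds exactly in expectation. Windows are
independent with no within-window recombination — the analysis treats
windows as exchangeable blocks, which is all the block bootstrap assumes —
and mutations fall on branches as Poisson(μ·L·branch length) at distinct
positions (infinite sites within a window). Haplotypes are paired into
diploids and phase is kept as ground truth. An external coalescent
simulator (msprime) with the identical demography serves as a
divergence oracle in the tests.

Defaults are the desk-scale study design: 10 diploids per ingroup
population plus one outgroup diploid, Ne = 10,000, split 50,000 generations,
outgroup 500,000 generations, μ = 3.5×10⁻⁹, 50 windows of 100 kb. Site
annotations are drawn clean — constant summed depth (20× per sample), MQ 60,
MQ0 0, balanced strand summaries, F = 0 — so no site-level rule fires unless
violations are planted; constant depth is deliberate, since any continuous
depth distribution would always lose ~5% of sites to the percentile rule
and bias distance denominators. The one realistic noise source kept on is
heterozygote allele depths, drawn Binomial(20, ½), which trips the
allele-balance rule for roughly 0.3% of het calls — the same order as the
0.02–0.15% seen at higher depth in real data. `plant_filter_violations`
overwrites annotations at disjoint random sites so each violates exactly
one named rule, returning the ledger for exact accounting tests.

The landmark simulator draws each specimen as a group template plus
isotropic Gaussian noise (default sd 0.01 shape units), then applies a
random rotation, translation and scale, recording the scale as the TPS
factor. The default templates are a stylised 15-landmark lateral fish body
differing along a single body-depth deformation axis by 0.08 shape units —
eight noise standard deviations, chosen so that group separation is a
geometric property of the configuration rather than a statistical accident
at the simulated sample sizes (20 per group).

What the simulators deliberately omit: recombination within windows,
migration and introgression, selection, sequencing-error models beyond the
planted mechanism, allometry and sexual dimorphism in shapes. Passing tests
therefore demonstrate correctness of the estimators under the stated
models, not robustness to those real-data complications.

## Problem sizes and numerical conventions

Simulation-backed tests use 4–10 diploids per population and 20–500 windows
of 100 kb, sizes at which the Monte-Carlo error of each tested expectation
is a few percent — comparisons use 3 standard errors computed from the
per-window spread. The split-time recovery study uses 500 windows and 10
replicate simulations per split depth (5,000; 10,000; 20,000 generations),
asserting ≤ 15% median relative error with the net correction and the
predicted ≈ +2Ne·g bias without it. Distance-matrix symmetry is enforced to
1e-12; NJ path-length oracles to 1e-9; GPA invariances to 1e-9. Degenerate
inputs fail loudly: zero-depth balance tests, zero total denominators,
zero-centroid-size configurations, unknown labels, paraphyletic groupings.
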