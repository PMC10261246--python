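# utaka

Genomic and morphometric separation of very recently diverged fish species,
built for the Lake Malawi "utaka" cichlids (*Copadichromis*) but applicable
to any pair of close congeners with whole-genome SNP data and landmark
photographs.

Recently separated species are hard cases: most genealogical history
predates the split, so individual gene trees rarely match the species tree
(incomplete lineage sorting), and raw genetic distances are dominated by
shared ancestral diversity. The package implements an analysis designed for
exactly this regime:

* **Hard site masking** of a multi-sample biallelic-SNP VCF: MQ0 fraction
  > 10%, RMS mapping quality < 50, strand mapping-quality bias (two-sample
  z-test, p < 0.001), summed depth outside the dataset-wide 2.5–97.5
  percentiles, heterozygous genotypes with allele-balance PHRED > 20
  (exact binomial), excess heterozygosity (inbreeding coefficient F below a
  floor), and > 20% missing genotypes.
* **Windowed divergence**: expected pairwise allele mismatches
  d(gᵢ, gⱼ) = (gᵢ(2−gⱼ) + gⱼ(2−gᵢ))/4 accumulated in 100-kb windows with
  per-pair accessible-site denominators, aggregated genome-wide as a ratio
  of sums (dₓᵧ per bp).
* **Split ("net") distances**: Nei's d_a form — each pair's mean
  within-individual heterozygosity subtracted from its between-individual
  distance, so that E[d] = 0 within a panmictic population and
  E[d] = 2μT between populations split T generations ago.
* **Neighbour-joining trees** (Saitou–Nei, deterministic tie-breaking),
  outgroup rooting, and **block-bootstrap node support** by resampling
  window distance matrices with replacement and rebuilding the tree per
  replicate; per-window ("local gene tree") support fractions quantify ILS.
* **Split-time dating**: t = g·h/μ from the mean tip height h of the split
  node of the rooted net tree, with mutation-rate uncertainty propagated as
  t·μ/μ_hi … t·μ/μ_lo (defaults: μ = 3.5×10⁻⁹/bp/generation,
  CI 1.6–4.7×10⁻⁹, generation time 3 years).
* **Geometric morphometrics**: TPS landmark I/O, centroid size,
  generalised Procrustes analysis (rotation-only, unit centroid size,
  principal-axis output orientation) and PCA of the Procrustes coordinates.
* **Synthetic data with known truth**: a two-population-plus-outgroup
  structured coalescent with independent 100-kb windows and infinite-sites
  mutation, a planted-violation generator for the filter rules, and a
  two-group landmark simulator under similarity-transform nuisance.

## Worked example

Simulate two populations (10 diploids each, Ne = 10,000) that split 50,000
generations ago plus one outgroup diploid, and run the genomic track:

```python
from utaka import (
    GenSimConfig, simulate_split_genotypes, build_accessibility,
    window_distances, aggregate, individual_heterozygosity, net_distance,
    neighbor_joining, root_by_outgroup, block_bootstrap_support,
    estimate_split_time, DatingConfig,
)
from utaka.containers import DistanceMatrix
from utaka.trees import nj_input

cfg = GenSimConfig(seed=1)  # 10+10 diploids + outgroup, T = 50,000 generations
matrix, truth = simulate_split_genotypes(cfg)
print(f"{matrix.n_sites} SNPs across {cfg.n_windows} windows")

mask = build_accessibility(None, matrix.chrom_lengths, cfg.window_size)
wds = window_distances(matrix, mask)
het = individual_heterozygosity(wds)
print(f"mean heterozygosity: {het.mean():.3e}")

net = net_distance(aggregate(wds), het)
clamped, _ = nj_input(net.values)
tree = root_by_outgroup(neighbor_joining(DistanceMatrix(net.labels, clamped)), "OUT1")

group_a = {s for s in matrix.samples if s.startswith("A")}
group_b = {s for s in matrix.samples if s.startswith("B")}
(support,) = block_bootstrap_support(wds, [group_a], replicates=200, seed=1, net=True)
print(f"bootstrap support for the A|B split: {support.support:.0f}%")

est = estimate_split_time(tree, group_a, group_b, DatingConfig())
print(f"split time: {est.t_years/1000:.0f} kya "
      f"(rate CI {est.ci_years[0]/1000:.0f}-{est.ci_years[1]/1000:.0f} kya); "
      f"truth: {truth.t_split * 3 / 1000:.0f} kya")
```

Output:

```
22906 SNPs across 50 windows
mean heterozygosity: 1.356e-04
bootstrap support for the A|B split: 100%
split time: 148 kya (rate CI 110-324 kya); truth: 150 kya
```

The heterozygosity matches the coalescent expectation 4·Ne·μ = 1.4×10⁻⁴;
the species bipartition gets full bootstrap support at this split depth; and
the net-divergence dating recovers the true 150 ka (50,000 generations ×
3 years) within ~1.5%. The confidence interval reflects only mutation-rate
uncertainty, by design.

The same workflow is scriptable from the shell (`utaka simulate genotypes`,
`utaka filter`, `utaka distances`, `utaka tree`, `utaka split-time`,
`utaka localtrees`, `utaka gm`, or `utaka analyse --config run.yaml` for the
whole pipeline with a manifest).

## Layout

- `src/utaka/filtering.py`, `vcfio.py` — masking rules, VCF I/O
- `src/utaka/distances.py` — windowed dₓᵧ, heterozygosity, net distances
- `src/utaka/trees.py` — NJ, rooting, bipartitions, block bootstrap, local trees
- `src/utaka/dating.py` — split-time estimation and rate-CI propagation
- `src/utaka/morphometrics.py` — TPS, GPA, shape PCA
- `src/utaka/simulate.py` — coalescent and landmark simulators
- `src/utaka/pipeline.py`, `cli.py` — orchestration and command line
- `docs/methods.md` — models, assumptions, parameter choices, limitations
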