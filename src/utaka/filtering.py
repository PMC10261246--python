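"""Hard site- and genotype-level masking of biallelic SNP matrices.

Seven rules are applied, mirroring the hard-filter stage of a short-read
variant-calling pipeline on a dense multi-sample callset:

1. MQ0 fraction — more than 10% of mapped reads with mapping quality zero;
2. low overall RMS mapping quality (< 50);
3. mapping quality significantly different between forward and reverse
   strand (two-sample z-test on per-strand summaries, p < 0.001);
4. summed depth over samples outside the dataset-wide 2.5–97.5 percentiles;
5. per genotype: heterozygous calls whose (ref, alt) allele depths fail an
   exact binomial balance test at PHRED > 20 are set to missing;
6. excess heterozygosity, inbreeding coefficient F below a floor (-0.2);
7. more than 20% missing genotypes, assessed after rule 5.

Rules 1–4 and 6–7 mask whole sites; rule 5 masks individual genotypes. All
site rules are pure predicates on the per-site annotations, so the retained
set does not depend on application order (rule 7 is defined to follow the
genotype-level rule 5). Depth percentiles are computed once, over all input
sites, before any masking.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from utaka.containers import MISSING, AccessibilityMask, GenotypeMatrix

RULE_NAMES = [
    "mq0_fraction",
    "low_mq",
    "strand_mq_bias",
    "depth_percentile",
    "allele_balance",  # genotype-level
    "excess_heterozygosity",
    "missingness",
]


@dataclass
class FilterConfig:
    """Thresholds for the masking rules (defaults follow the pipeline above)."""

    mq0_max: float = 0.10
    mq_min: float = 50.0
    strand_p_max: float = 0.001
    depth_lo_pct: float = 2.5
    depth_hi_pct: float = 97.5
    ab_phred_max: float = 20.0
    inbreeding_min: float = -0.2
    missing_max: float = 0.20
    window_size: int = 100_000

    def validate(self) -> None:
        for name in ("mq0_max", "mq_min", "strand_p_max", "depth_lo_pct",
                     "depth_hi_pct", "ab_phred_max", "inbreeding_min",
                     "missing_max"):
            if not np.isfinite(getattr(self, name)):
                raise ValueError(f"filter threshold {name} must be finite")
        if not (0 <= self.depth_lo_pct < self.depth_hi_pct <= 100):
            raise ValueError("require 0 <= depth_lo_pct < depth_hi_pct <= 100")
        if self.window_size <= 0:
            raise ValueError("window_size must be positive")


@dataclass
class FilterReport:
    """Accounting of masked sites per rule and masked genotypes per sample."""

    sites_total: int
    sites_retained: int
    site_counts: dict[str, int]
    het_genotypes_masked: dict[str, int]
    het_genotypes_total: dict[str, int]
    ab_skipped_missing_ad: int = 0

    @property
    def masked_het_fraction(self) -> dict[str, float]:
        return {
            s: (self.het_genotypes_masked[s] / t if t else 0.0)
            for s, t in self.het_genotypes_total.items()
        }

    def to_frame(self) -> pd.DataFrame:
        rows = [(rule, self.site_counts.get(rule, 0)) for rule in RULE_NAMES
                if rule != "allele_balance"]
        rows.append(("allele_balance_genotypes", sum(self.het_genotypes_masked.values())))
        rows.append(("sites_total", self.sites_total))
        rows.append(("sites_retained", self.sites_retained))
        return pd.DataFrame(rows, columns=["rule", "count"])

    def log_lines(self) -> list[str]:
        lines = [f"input sites: {self.sites_total}",
                 f"retained sites: {self.sites_retained}"]
        for rule in RULE_NAMES:
            if rule == "allele_balance":
                continue
            lines.append(f"masked by {rule}: {self.site_counts.get(rule, 0)}")
        for s, frac in self.masked_het_fraction.items():
            lines.append(
                f"allele-balance masked hets for {s}: "
                f"{self.het_genotypes_masked[s]} ({100 * frac:.3f}% of het calls)"
            )
        if self.ab_skipped_missing_ad:
            lines.append(f"genotypes without AD skipped by allele-balance rule: "
                         f"{self.ab_skipped_missing_ad}")
        return lines


def allele_balance_phred(ref_count: int, alt_count: int) -> float:
    """PHRED-scaled two-sided exact binomial test of allelic balance.

    Returns ``-10 * log10(p)`` where ``p`` is the probability, under
    Binomial(n, 1/2), of a ref/alt split at least as extreme as observed.
    """
    n = ref_count + alt_count
    if n < 1:
        raise ValueError("allele balance test undefined at zero depth")
    if ref_count < 0 or alt_count < 0:
        raise ValueError("allele depths must be non-negative")
    p = _balance_pvalue(np.asarray([ref_count]), np.asarray([n]))[0]
    return float(-10.0 * np.log10(p))


def _balance_pvalue(k: np.ndarray, n: np.ndarray) -> np.ndarray:
    # two-sided exact binomial at p = 1/2; symmetry makes this 2*CDF(min(k, n-k))
    m = np.minimum(k, n - k)
    return np.minimum(1.0, 2.0 * stats.binom.cdf(m, n, 0.5))


def inbreeding_coefficient(hom_ref: int, het: int, hom_alt: int) -> float:
    """F = 1 - H_obs / H_exp from genotype counts at one site.

    Monomorphic sites (one allele absent) carry no information on excess
    heterozygosity; F is defined as 0 there.
    """
    n = hom_ref + het + hom_alt
    if n < 1:
        raise ValueError("need at least one genotyped sample")
    p = (2 * hom_alt + het) / (2 * n)
    h_exp = 2 * p * (1 - p)
    if h_exp == 0.0:
        return 0.0
    return 1.0 - (het / n) / h_exp


def strand_mq_pvalue(
    fwd_mean: float, fwd_sd: float, fwd_n: float,
    rev_mean: float, rev_sd: float, rev_n: float,
) -> float:
    """Two-sided two-sample z-test on per-strand mapping-quality summaries."""
    if fwd_n <= 0 or rev_n <= 0:
        return 1.0
    se2 = fwd_sd**2 / fwd_n + rev_sd**2 / rev_n
    if se2 == 0.0:
        return 1.0 if fwd_mean == rev_mean else 0.0
    z = (fwd_mean - rev_mean) / np.sqrt(se2)
    return float(2.0 * stats.norm.sf(abs(z)))


def _site_inbreeding(matrix: GenotypeMatrix) -> np.ndarray:
    """Per-site F, from the annotation column where present else from genotypes."""
    stored = matrix.sites["inbreeding_coeff"].to_numpy(dtype=float)
    out = stored.copy()
    need = ~np.isfinite(stored)
    if need.any():
        g = matrix.genotypes[need]
        n0 = (g == 0).sum(axis=1).astype(float)
        n1 = (g == 1).sum(axis=1).astype(float)
        n2 = (g == 2).sum(axis=1).astype(float)
        n = n0 + n1 + n2
        with np.errstate(divide="ignore", invalid="ignore"):
            p = (2 * n2 + n1) / (2 * n)
            h_exp = 2 * p * (1 - p)
            f = 1.0 - (n1 / n) / h_exp
        f[(h_exp == 0) | (n == 0)] = 0.0
        out[need] = f
    return out


def site_masks(
    matrix: GenotypeMatrix, config: FilterConfig | None = None
) -> tuple[GenotypeMatrix, FilterReport]:
    """Apply all masking rules; return the filtered matrix and a report.

    The returned matrix contains only retained sites, with rule-5
    allele-balance-failing heterozygous genotypes set to missing.
    """
    config = config or FilterConfig()
    config.validate()
    if matrix.n_sites == 0:
        raise ValueError("empty genotype matrix")

    sites = matrix.sites
    counts: dict[str, int] = {}

    # rules 1-2: MQ0 fraction and overall mapping quality
    mq0 = sites["mq0_fraction"].to_numpy(dtype=float)
    mq = sites["mq"].to_numpy(dtype=float)
    m1 = mq0 > config.mq0_max
    m2 = mq < config.mq_min

    # rule 3: strand MQ difference z-test from (mean, sd, n) summaries
    fm = sites["fwd_mq_mean"].to_numpy(dtype=float)
    fs = sites["fwd_mq_sd"].to_numpy(dtype=float)
    fn = sites["fwd_n"].to_numpy(dtype=float)
    rm = sites["rev_mq_mean"].to_numpy(dtype=float)
    rs = sites["rev_mq_sd"].to_numpy(dtype=float)
    rn = sites["rev_n"].to_numpy(dtype=float)
    have_strand = np.isfinite(fm) & np.isfinite(rm) & (fn > 0) & (rn > 0)
    pvals = np.ones(matrix.n_sites)
    if have_strand.any():
        se2 = np.where(have_strand, fs**2 / np.maximum(fn, 1) + rs**2 / np.maximum(rn, 1), 1.0)
        with np.errstate(divide="ignore", invalid="ignore"):
            z = (fm - rm) / np.sqrt(se2)
        zero_se = have_strand & (se2 == 0)
        z = np.where(zero_se & (fm != rm), np.inf, np.where(zero_se, 0.0, z))
        pvals = np.where(have_strand, 2.0 * stats.norm.sf(np.abs(z)), 1.0)
    m3 = pvals < config.strand_p_max

    # rule 4: dataset-wide depth percentiles computed before any masking
    depth = sites["total_depth"].to_numpy(dtype=float)
    lo = np.percentile(depth, config.depth_lo_pct)
    hi = np.percentile(depth, config.depth_hi_pct)
    m4 = (depth < lo) | (depth > hi)

    # rule 5 (genotype level): allele-balance PHRED of het calls
    genotypes = matrix.genotypes.copy()
    het_masked = {s: 0 for s in matrix.samples}
    het_total = {
        s: int((matrix.genotypes[:, j] == 1).sum())
        for j, s in enumerate(matrix.samples)
    }
    skipped = 0
    if matrix.allele_depths is not None:
        ad = matrix.allele_depths
        het = genotypes == 1
        has_ad = (ad[:, :, 0] >= 0) & (ad[:, :, 1] >= 0) & (ad.sum(axis=2) >= 1)
        skipped = int((het & ~has_ad).sum())
        test = het & has_ad
        if test.any():
            i, j = np.nonzero(test)
            k = ad[i, j, 0].astype(np.int64)
            n = (ad[i, j, 0] + ad[i, j, 1]).astype(np.int64)
            phred = -10.0 * np.log10(_balance_pvalue(k, n))
            fail = phred > config.ab_phred_max
            genotypes[i[fail], j[fail]] = MISSING
            for jj in j[fail]:
                het_masked[matrix.samples[jj]] += 1
    else:
        skipped = int((genotypes == 1).sum())

    # rule 6: excess heterozygosity (F below floor)
    f = _site_inbreeding(matrix)
    m6 = f < config.inbreeding_min

    # rule 7: missingness after genotype-level masking
    missing_frac = (genotypes == MISSING).mean(axis=1)
    m7 = missing_frac > config.missing_max

    counts["mq0_fraction"] = int(m1.sum())
    counts["low_mq"] = int(m2.sum())
    counts["strand_mq_bias"] = int(m3.sum())
    counts["depth_percentile"] = int(m4.sum())
    counts["excess_heterozygosity"] = int(m6.sum())
    counts["missingness"] = int(m7.sum())

    masked = m1 | m2 | m3 | m4 | m6 | m7
    keep = ~masked

    out = matrix.subset_sites(keep)
    out.genotypes = genotypes[keep]
    if out.phased_haplotypes is not None:
        # genotype-level masking invalidates phase at masked calls
        newly_missing = (out.genotypes == MISSING) & (
            matrix.genotypes[keep] != MISSING
        )
        out.phased_haplotypes = out.phased_haplotypes.copy()
        out.phased_haplotypes[newly_missing] = 0

    report = FilterReport(
        sites_total=matrix.n_sites,
        sites_retained=int(keep.sum()),
        site_counts=counts,
        het_genotypes_masked=het_masked,
        het_genotypes_total=het_total,
        ab_skipped_missing_ad=skipped,
    )
    return out, report


def build_accessibility(
    mask_input: str | pd.DataFrame | None,
    chrom_lengths: dict[str, int],
    window_size: int = 100_000,
) -> AccessibilityMask:
    """Per-window accessible-base counts to use as divergence denominators.

    ``mask_input`` may be ``None`` (every base accessible), a BED file path or
    DataFrame of accessible intervals (0-based half-open), or a DataFrame of
    per-window counts with columns (chrom, start, accessible).
    """
    if mask_input is None:
        return AccessibilityMask.full(chrom_lengths, window_size)

    if isinstance(mask_input, pd.DataFrame) and "accessible" in mask_input.columns:
        return AccessibilityMask(window_size, mask_input.reset_index(drop=True))

    if isinstance(mask_input, str):
        bed = pd.read_csv(
            mask_input, sep="\t", header=None, usecols=[0, 1, 2],
            names=["chrom", "start", "end"], dtype={0: str}, comment="#",
        )
    else:
        bed = mask_input.copy()
        bed.columns = ["chrom", "start", "end"][: len(bed.columns)]

    full = AccessibilityMask.full(chrom_lengths, window_size)
    counts = {key: 0 for key in full.lookup()}
    for row in bed.itertuples():
        chrom, start, end = str(row.chrom), int(row.start), int(row.end)
        if chrom not in chrom_lengths:
            raise ValueError(f"BED interval on unknown chromosome {chrom!r}")
        if start < 0 or end > chrom_lengths[chrom] or start >= end:
            raise ValueError(
                f"BED interval {chrom}:{start}-{end} outside chromosome bounds"
            )
        w0 = start // window_size
        w1 = (end - 1) // window_size
        for w in range(w0, w1 + 1):
            wlo, whi = w * window_size, (w + 1) * window_size
            counts[(chrom, wlo)] += min(end, whi) - max(start, wlo)

    table = full.table.copy()
    table["accessible"] = [
        counts[(str(r.chrom), int(r.start))] for r in table.itertuples()
    ]
    return AccessibilityMask(window_size, table)
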