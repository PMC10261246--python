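"""Core data containers shared by the genomic modules.

The central object is :class:`GenotypeMatrix` — biallelic SNP sites by diploid
samples, with the per-site annotations the masking rules consume (depth,
mapping quality, MQ0 fraction, per-strand MQ summaries, inbreeding
coefficient) and optional per-genotype allele depths and phased haplotypes.
Coordinates follow VCF convention (1-based positions); windows are 0-based
half-open ``[w*S, (w+1)*S)``, so a site at position ``p`` falls in window
``(p - 1) // S``.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

MISSING = -1  # genotype code for a missing call

#: per-site annotation columns carried in GenotypeMatrix.sites
SITE_COLUMNS = [
    "chrom",
    "pos",
    "ref",
    "alt",
    "total_depth",
    "mq",
    "mq0_fraction",
    "fwd_mq_mean",
    "fwd_mq_sd",
    "fwd_n",
    "rev_mq_mean",
    "rev_mq_sd",
    "rev_n",
    "inbreeding_coeff",
]


@dataclass
class GenotypeMatrix:
    """Biallelic SNP sites x diploid samples.

    Parameters
    ----------
    samples
        Ordered sample identifiers.
    sites
        DataFrame with one row per site, columns :data:`SITE_COLUMNS`
        (annotation columns may be NaN where unknown).
    genotypes
        ``(n_sites, n_samples)`` int8 array counting alternate alleles
        (0, 1, 2) with :data:`MISSING` for uncalled genotypes.
    allele_depths
        Optional ``(n_sites, n_samples, 2)`` array of (ref, alt) read counts;
        entries of -1 mean the AD field was absent for that genotype.
    phased_haplotypes
        Optional ``(n_sites, n_samples, 2)`` array of haplotype alleles in
        {0, 1}; where present their sum equals the genotype code.
    chrom_lengths
        Chromosome lengths in bp, used to tile windows.
    """

    samples: list[str]
    sites: pd.DataFrame
    genotypes: np.ndarray
    allele_depths: np.ndarray | None = None
    phased_haplotypes: np.ndarray | None = None
    chrom_lengths: dict[str, int] = field(default_factory=dict)
    dropped_records: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.genotypes = np.asarray(self.genotypes, dtype=np.int8)
        if self.genotypes.shape != (len(self.sites), len(self.samples)):
            raise ValueError(
                f"genotypes shape {self.genotypes.shape} does not match "
                f"{len(self.sites)} sites x {len(self.samples)} samples"
            )
        if not (self.sites["pos"] >= 1).all():
            raise ValueError("VCF positions are 1-based; found pos < 1")
        if self.phased_haplotypes is not None:
            hap_sum = self.phased_haplotypes.sum(axis=2)
            called = self.genotypes != MISSING
            if not np.array_equal(hap_sum[called], self.genotypes[called]):
                raise ValueError("phased haplotypes inconsistent with genotype codes")

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def subset_sites(self, keep: np.ndarray) -> "GenotypeMatrix":
        """Return a new matrix restricted to sites where ``keep`` is True."""
        keep = np.asarray(keep, dtype=bool)
        return GenotypeMatrix(
            samples=list(self.samples),
            sites=self.sites.loc[keep].reset_index(drop=True),
            genotypes=self.genotypes[keep],
            allele_depths=None if self.allele_depths is None else self.allele_depths[keep],
            phased_haplotypes=(
                None if self.phased_haplotypes is None else self.phased_haplotypes[keep]
            ),
            chrom_lengths=dict(self.chrom_lengths),
            dropped_records=dict(self.dropped_records),
        )

    # -- TSV serialisation (documented format: site annotation columns followed
    #    by one genotype-code column per sample; missing = -1) ----------------

    def to_tsv(self, path: str) -> None:
        df = self.sites.copy()
        for j, s in enumerate(self.samples):
            df[f"gt:{s}"] = self.genotypes[:, j]
        header = "#chrom_lengths\t" + ",".join(
            f"{c}:{l}" for c, l in self.chrom_lengths.items()
        )
        with open(path, "w") as fh:
            fh.write(header + "\n")
            df.to_csv(fh, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str) -> "GenotypeMatrix":
        with open(path) as fh:
            first = fh.readline()
            body = fh.read()
        chrom_lengths: dict[str, int] = {}
        if first.startswith("#chrom_lengths"):
            spec = first.split("\t", 1)[1].strip()
            if spec:
                for item in spec.split(","):
                    c, l = item.rsplit(":", 1)
                    chrom_lengths[c] = int(l)
        df = pd.read_csv(io.StringIO(body), sep="\t", dtype={"chrom": str})
        gt_cols = [c for c in df.columns if c.startswith("gt:")]
        samples = [c[3:] for c in gt_cols]
        genotypes = df[gt_cols].to_numpy(dtype=np.int8)
        sites = df[[c for c in SITE_COLUMNS if c in df.columns]].reset_index(drop=True)
        return cls(
            samples=samples,
            sites=sites,
            genotypes=genotypes,
            chrom_lengths=chrom_lengths,
        )


def window_index(pos: np.ndarray | int, window_size: int) -> np.ndarray | int:
    """Window index of a 1-based position under 0-based half-open tiling."""
    return (np.asarray(pos) - 1) // window_size


@dataclass
class AccessibilityMask:
    """Per-window counts of accessible (callable) bases.

    ``table`` has columns ``chrom``, ``start`` (0-based window start) and
    ``accessible``; windows tile each chromosome without overlap and the
    counts serve as divergence denominators.
    """

    window_size: int
    table: pd.DataFrame

    def __post_init__(self) -> None:
        acc = self.table["accessible"]
        if (acc < 0).any() or (acc > self.window_size).any():
            raise ValueError("accessible counts must lie in [0, window_size]")

    @classmethod
    def full(cls, chrom_lengths: dict[str, int], window_size: int) -> "AccessibilityMask":
        """Every base accessible: counts are window overlaps with the chromosome."""
        rows = []
        for chrom, length in chrom_lengths.items():
            for start in range(0, length, window_size):
                rows.append((chrom, start, min(window_size, length - start)))
        return cls(window_size, pd.DataFrame(rows, columns=["chrom", "start", "accessible"]))

    def lookup(self) -> dict[tuple[str, int], int]:
        return {
            (str(r.chrom), int(r.start)): int(r.accessible)
            for r in self.table.itertuples()
        }

    def to_tsv(self, path: str) -> None:
        self.table.to_csv(path, sep="\t", index=False,
                          header=["chrom", "window_start", "accessible_bases"])

    @classmethod
    def from_tsv(cls, path: str, window_size: int) -> "AccessibilityMask":
        df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
        df.columns = ["chrom", "start", "accessible"]
        return cls(window_size, df)


@dataclass
class DistanceMatrix:
    """Labelled symmetric matrix of per-bp genetic distances."""

    labels: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if self.values.shape != (n, n):
            raise ValueError("distance matrix shape does not match labels")
        if not np.allclose(self.values, self.values.T, atol=1e-12):
            raise ValueError("distance matrix is not symmetric")
        if not np.allclose(np.diag(self.values), 0.0, atol=1e-15):
            raise ValueError("distance matrix diagonal must be zero")

    def to_tsv(self, path: str) -> None:
        pd.DataFrame(self.values, index=self.labels, columns=self.labels).to_csv(
            path, sep="\t"
        )

    def to_phylip(self, path: str) -> None:
        with open(path, "w") as fh:
            fh.write(f"{len(self.labels)}\n")
            for lab, row in zip(self.labels, self.values):
                fh.write(lab + "  " + "  ".join(f"{v:.10g}" for v in row) + "\n")

    @classmethod
    def from_tsv(cls, path: str) -> "DistanceMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(labels=[str(c) for c in df.columns], values=df.to_numpy(dtype=float))
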