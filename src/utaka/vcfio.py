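"""VCF input and output for the filtering pipeline.

Reading uses cyvcf2; only biallelic SNP records are retained (indels and
multiallelic records are dropped and counted). Writing emits a plain-text,
standards-conformant VCF with GT and AD per sample and the INFO annotations
the masking rules read, so a simulated matrix round-trips exactly.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from cyvcf2 import VCF

from utaka.containers import MISSING, GenotypeMatrix

_BASES = {"A", "C", "G", "T"}


@dataclass
class VcfInfoKeys:
    """Names of the INFO fields carrying per-site annotations.

    ``mq0_fraction`` is preferred; if absent, ``mq0_count`` / ``depth`` is
    used. The per-strand keys each hold a (mean, sd, n) triple of mapping
    qualities for forward and reverse reads.
    """

    depth: str = "DP"
    mq: str = "MQ"
    mq0_fraction: str = "MQ0F"
    mq0_count: str = "MQ0"
    strand_fwd: str = "MQSF"
    strand_rev: str = "MQSR"
    inbreeding: str = "InbreedingCoeff"


def load_biallelic_snps(
    vcf_path: str, info_keys: VcfInfoKeys | None = None
) -> GenotypeMatrix:
    """Load biallelic SNPs from a VCF (plain or bgzipped) into a matrix.

    Multiallelic records and indels are dropped; the counts are recorded in
    ``GenotypeMatrix.dropped_records``. Missing genotypes are coded as -1.
    """
    keys = info_keys or VcfInfoKeys()
    if not os.path.exists(vcf_path):
        raise FileNotFoundError(vcf_path)
    vcf = VCF(vcf_path)
    samples = list(vcf.samples)
    if not samples:
        raise ValueError(f"{vcf_path}: VCF carries no samples / GT fields")

    chrom_lengths = dict(zip(vcf.seqnames, vcf.seqlens)) if vcf.seqlens else {}

    rows = []
    gts: list[np.ndarray] = []
    phased_rows: list[np.ndarray] = []
    ads: list[np.ndarray] = []
    any_phased = False
    dropped = {"multiallelic": 0, "indel": 0}

    for var in vcf:
        if len(var.ALT) != 1:
            dropped["multiallelic"] += 1
            continue
        if var.REF.upper() not in _BASES or var.ALT[0].upper() not in _BASES:
            dropped["indel"] += 1
            continue
        geno = var.genotypes
        if geno is None or len(geno) != len(samples):
            raise ValueError(f"{vcf_path}: record at {var.CHROM}:{var.POS} lacks GT")
        g = np.full(len(samples), MISSING, dtype=np.int8)
        hap = np.zeros((len(samples), 2), dtype=np.int8)
        for j, call in enumerate(geno):
            a, b = call[0], call[1]
            if a < 0 or b < 0:
                continue
            g[j] = a + b
            hap[j] = (a, b)
            if call[2]:
                any_phased = True
        gts.append(g)
        phased_rows.append(hap)

        try:
            ad = var.format("AD")
        except KeyError:  # AD not declared in the header
            ad = None
        if ad is None:
            ads.append(np.full((len(samples), 2), -1, dtype=np.int32))
        else:
            ad = np.asarray(ad, dtype=np.int32)[:, :2]
            ad[ad < 0] = -1
            ads.append(ad)

        info = var.INFO
        mq0f = info.get(keys.mq0_fraction)
        if mq0f is None:
            mq0 = info.get(keys.mq0_count)
            dp = info.get(keys.depth)
            mq0f = (mq0 / dp) if (mq0 is not None and dp) else np.nan
        fwd = _triple(info.get(keys.strand_fwd))
        rev = _triple(info.get(keys.strand_rev))
        rows.append(
            (
                var.CHROM,
                var.POS,
                var.REF.upper(),
                var.ALT[0].upper(),
                _scalar(info.get(keys.depth)),
                _scalar(info.get(keys.mq)),
                float(mq0f) if mq0f is not None else np.nan,
                *fwd,
                *rev,
                _scalar(info.get(keys.inbreeding)),
            )
        )

    from utaka.containers import SITE_COLUMNS

    sites = pd.DataFrame(rows, columns=SITE_COLUMNS)
    genotypes = (
        np.vstack(gts) if gts else np.zeros((0, len(samples)), dtype=np.int8)
    )
    allele_depths = (
        np.stack(ads) if ads else np.zeros((0, len(samples), 2), dtype=np.int32)
    )
    phased = np.stack(phased_rows) if (phased_rows and any_phased) else None
    return GenotypeMatrix(
        samples=samples,
        sites=sites,
        genotypes=genotypes,
        allele_depths=allele_depths,
        phased_haplotypes=phased,
        chrom_lengths=chrom_lengths,
        dropped_records=dropped,
    )


def _scalar(v) -> float:
    if v is None:
        return np.nan
    if isinstance(v, (tuple, list, np.ndarray)):
        v = v[0]
    return float(v)


def _triple(v) -> tuple[float, float, float]:
    if v is None:
        return (np.nan, np.nan, np.nan)
    if isinstance(v, str):
        parts = v.split(",")
    else:
        parts = list(np.atleast_1d(v))
    if len(parts) != 3:
        return (np.nan, np.nan, np.nan)
    return tuple(float(x) for x in parts)  # type: ignore[return-value]


_HEADER_META = """##fileformat=VCFv4.2
##source=utaka
##INFO=<ID=DP,Number=1,Type=Integer,Description="Total read depth over samples">
##INFO=<ID=MQ,Number=1,Type=Float,Description="RMS mapping quality">
##INFO=<ID=MQ0F,Number=1,Type=Float,Description="Fraction of reads with mapping quality zero">
##INFO=<ID=MQSF,Number=3,Type=Float,Description="Forward-strand MQ mean, sd, read count">
##INFO=<ID=MQSR,Number=3,Type=Float,Description="Reverse-strand MQ mean, sd, read count">
##INFO=<ID=InbreedingCoeff,Number=1,Type=Float,Description="Site inbreeding coefficient F">
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths (ref, alt)">
"""


def write_vcf(matrix: GenotypeMatrix, path: str) -> None:
    """Serialise a genotype matrix as a plain-text VCF.

    Unphased diploid genotypes are written unless phased haplotypes are
    present, in which case phase is preserved with ``|`` separators. Missing
    genotypes are written as ``./.``.
    """
    sites = matrix.sites
    with open(path, "w") as fh:
        fh.write(_HEADER_META)
        for chrom, length in matrix.chrom_lengths.items():
            fh.write(f"##contig=<ID={chrom},length={length}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(matrix.samples)
            + "\n"
        )
        phased = matrix.phased_haplotypes
        ad_arr = matrix.allele_depths
        for i, row in enumerate(sites.itertuples()):
            info = []
            if np.isfinite(row.total_depth):
                info.append(f"DP={int(row.total_depth)}")
            if np.isfinite(row.mq):
                info.append(f"MQ={row.mq:g}")
            if np.isfinite(row.mq0_fraction):
                info.append(f"MQ0F={row.mq0_fraction:g}")
            if np.isfinite(row.fwd_mq_mean):
                info.append(f"MQSF={row.fwd_mq_mean:g},{row.fwd_mq_sd:g},{row.fwd_n:g}")
            if np.isfinite(row.rev_mq_mean):
                info.append(f"MQSR={row.rev_mq_mean:g},{row.rev_mq_sd:g},{row.rev_n:g}")
            if np.isfinite(row.inbreeding_coeff):
                info.append(f"InbreedingCoeff={row.inbreeding_coeff:g}")
            cols = [
                str(row.chrom),
                str(int(row.pos)),
                ".",
                row.ref,
                row.alt,
                ".",
                "PASS",
                ";".join(info) if info else ".",
                "GT:AD" if ad_arr is not None else "GT",
            ]
            for j in range(matrix.n_samples):
                g = matrix.genotypes[i, j]
                if g == MISSING:
                    gt = "./."
                elif phased is not None:
                    gt = f"{phased[i, j, 0]}|{phased[i, j, 1]}"
                else:
                    gt = {0: "0/0", 1: "0/1", 2: "1/1"}[int(g)]
                if ad_arr is not None:
                    r, a = ad_arr[i, j]
                    ad = ".,." if (r < 0 or a < 0) else f"{r},{a}"
                    cols.append(f"{gt}:{ad}")
                else:
                    cols.append(gt)
            fh.write("\t".join(cols) + "\n")
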