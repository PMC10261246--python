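"""Windowed pairwise sequence differences and net (split-tree) distances.

Pairwise differences are expected allele mismatches between two diploids,
averaged over haplotypes: for genotype codes ``g_i, g_j`` (alt-allele counts)

    d(g_i, g_j) = (g_i * (2 - g_j) + g_j * (2 - g_i)) / 4,

the mean mismatch over the four haplotype pairings (equivalently, over the
two possible phase alignments), so no phasing is required. Differences and
accessible-site denominators are accumulated per 100-kb window; genome-wide
distances are ratio-of-sums over windows, which makes the aggregate
invariant to how sites are partitioned into windows.

The "split tree" distance subtracts the mean of each pair's within-individual
heterozygosities from the between-individual distance (the net-divergence
d_a form), removing the shared ancestral-coalescence component so that the
expected net distance between two members of one panmictic population is 0
and the expected cross-population net distance is 2*mu*T.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from utaka.containers import (
    MISSING,
    AccessibilityMask,
    DistanceMatrix,
    GenotypeMatrix,
    window_index,
)


@dataclass
class WindowDistanceSet:
    """Per-window pairwise difference counts and denominators.

    ``diff_counts``/``pair_denominators`` are ``(n_windows, n, n)`` symmetric
    arrays; ``het_counts``/``het_denominators`` are ``(n_windows, n)``.
    Denominators count accessible sites usable for each pair (sites missing
    in either member are excluded).
    """

    samples: list[str]
    windows: list[tuple[str, int]]
    diff_counts: np.ndarray
    pair_denominators: np.ndarray
    het_counts: np.ndarray
    het_denominators: np.ndarray

    @property
    def n_windows(self) -> int:
        return len(self.windows)

    def to_long_frame(self) -> pd.DataFrame:
        rows = []
        n = len(self.samples)
        for w, (chrom, start) in enumerate(self.windows):
            for i in range(n):
                for j in range(i + 1, n):
                    rows.append(
                        (chrom, start, self.samples[i], self.samples[j],
                         self.diff_counts[w, i, j], self.pair_denominators[w, i, j])
                    )
        return pd.DataFrame(
            rows, columns=["chrom", "start", "sample_i", "sample_j", "diffs", "denom"]
        )


def genotype_difference(g_i: int, g_j: int) -> float:
    """Expected per-site allele mismatch between two diploid genotypes."""
    if g_i not in (0, 1, 2) or g_j not in (0, 1, 2):
        raise ValueError("genotype codes must be 0, 1 or 2 (exclude missing)")
    return (g_i * (2 - g_j) + g_j * (2 - g_i)) / 4.0


def window_distances(
    matrix: GenotypeMatrix, mask: AccessibilityMask
) -> WindowDistanceSet:
    """Accumulate pairwise differences and denominators per window.

    Every window of the accessibility mask is represented, including windows
    without SNPs (invariant sequence carries zero differences but full
    denominators). A site falling outside the mask's windows is an error.
    """
    n = matrix.n_samples
    lut = mask.lookup()
    win_order = [(str(r.chrom), int(r.start)) for r in mask.table.itertuples()]
    win_pos = {w: k for k, w in enumerate(win_order)}
    W = len(win_order)
    S = mask.window_size

    diff = np.zeros((W, n, n))
    denom = np.zeros((W, n, n))
    hets = np.zeros((W, n))
    het_denom = np.zeros((W, n))
    for k, w in enumerate(win_order):
        denom[k, :, :] = lut[w]
        np.fill_diagonal(denom[k], 0.0)
        het_denom[k, :] = lut[w]

    chroms = matrix.sites["chrom"].astype(str).to_numpy()
    starts = window_index(matrix.sites["pos"].to_numpy(), S) * S

    G = matrix.genotypes.astype(np.float64)
    valid = matrix.genotypes != MISSING

    # group sites by window
    keys = np.empty(matrix.n_sites, dtype=np.int64)
    for i, (c, s) in enumerate(zip(chroms, starts)):
        key = (c, int(s))
        if key not in win_pos:
            raise ValueError(
                f"site at {c}:{int(matrix.sites['pos'].iloc[i])} falls outside "
                "the accessibility-mask windows"
            )
        keys[i] = win_pos[key]

    order = np.argsort(keys, kind="stable")
    boundaries = np.searchsorted(keys[order], np.arange(W + 1))
    for k in range(W):
        idx = order[boundaries[k]:boundaries[k + 1]]
        if idx.size == 0:
            continue
        g = G[idx]
        v = valid[idx].astype(np.float64)
        x = np.where(valid[idx], g, 0.0)
        y = np.where(valid[idx], 2.0 - g, 0.0)
        m1 = x.T @ y
        diff[k] = (m1 + m1.T) / 4.0
        np.fill_diagonal(diff[k], 0.0)
        both = v.T @ v  # sites where both members are called
        # denominator: accessible count minus sites missing in either member
        denom[k] -= idx.size - both
        np.fill_diagonal(denom[k], 0.0)
        hets[k] = (np.where(valid[idx], g, -1.0) == 1.0).sum(axis=0)
        het_denom[k] -= (~valid[idx]).sum(axis=0)

    return WindowDistanceSet(
        samples=list(matrix.samples),
        windows=win_order,
        diff_counts=diff,
        pair_denominators=denom,
        het_counts=hets,
        het_denominators=het_denom,
    )


def individual_heterozygosity(wds: WindowDistanceSet) -> pd.Series:
    """Per-sample heterozygosity per accessible bp (ratio of sums)."""
    num = wds.het_counts.sum(axis=0)
    den = wds.het_denominators.sum(axis=0)
    if (den <= 0).any():
        bad = [s for s, d in zip(wds.samples, den) if d <= 0]
        raise ValueError(f"zero accessible denominator for samples {bad}")
    return pd.Series(num / den, index=wds.samples, name="heterozygosity")


def aggregate(wds: WindowDistanceSet) -> DistanceMatrix:
    """Genome-wide per-bp distances: sum of differences over sum of denominators."""
    num = wds.diff_counts.sum(axis=0)
    den = wds.pair_denominators.sum(axis=0)
    n = len(wds.samples)
    off = ~np.eye(n, dtype=bool)
    if (den[off] <= 0).any():
        raise ValueError("sample pair with zero total accessible denominator")
    values = np.zeros((n, n))
    values[off] = num[off] / den[off]
    return DistanceMatrix(labels=list(wds.samples), values=values)


def net_distance(raw: DistanceMatrix, het: pd.Series) -> DistanceMatrix:
    """Heterozygosity-corrected (net, d_a-style) distances.

    Subtracts the mean of the pair's two within-individual heterozygosities
    from each between-individual distance. Small negative values (sampling
    noise) are kept here; they are clamped to zero only when a matrix is fed
    to neighbour joining.
    """
    if list(het.index) != list(raw.labels):
        raise ValueError("heterozygosity labels do not match distance labels")
    h = het.to_numpy(dtype=float)
    corr = (h[:, None] + h[None, :]) / 2.0
    values = raw.values - corr
    np.fill_diagonal(values, 0.0)
    return DistanceMatrix(labels=list(raw.labels), values=values)
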