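"""Windowed pairwise differences, heterozygosity, aggregation, net distances."""

import numpy as np
import pandas as pd
import pytest

from utaka.containers import AccessibilityMask, SITE_COLUMNS, GenotypeMatrix
from utaka.distances import (
    aggregate,
    genotype_difference,
    individual_heterozygosity,
    net_distance,
    window_distances,
)
from utaka.filtering import build_accessibility
from utaka.simulate import GenSimConfig, simulate_split_genotypes


def tiny_matrix(genotypes, window_size=100, chrom_len=100, positions=None):
    genotypes = np.asarray(genotypes, dtype=np.int8)
    n_sites, n_samples = genotypes.shape
    pos = positions if positions is not None else np.arange(1, n_sites + 1)
    sites = pd.DataFrame(
        {
            "chrom": "1", "pos": pos, "ref": "A", "alt": "T",
            "total_depth": 100.0, "mq": 60.0, "mq0_fraction": 0.0,
            "fwd_mq_mean": 60.0, "fwd_mq_sd": 2.0, "fwd_n": 50.0,
            "rev_mq_mean": 60.0, "rev_mq_sd": 2.0, "rev_n": 50.0,
            "inbreeding_coeff": 0.0,
        },
        columns=SITE_COLUMNS,
    )
    return GenotypeMatrix(
        samples=[f"s{i}" for i in range(n_samples)],
        sites=sites,
        genotypes=genotypes,
        chrom_lengths={"1": chrom_len},
    )


@pytest.mark.parametrize(
    "gi,gj,expected",
    [(0, 0, 0.0), (2, 2, 0.0), (0, 2, 1.0), (2, 0, 1.0),
     (0, 1, 0.5), (1, 2, 0.5), (1, 1, 0.5)],
)
def test_genotype_difference_values(gi, gj, expected):
    assert genotype_difference(gi, gj) == expected


def test_genotype_difference_rejects_missing():
    with pytest.raises(ValueError):
        genotype_difference(-1, 0)


def test_genotype_difference_equals_haplotype_pairing_mean():
    """The genotype formula is the mean mismatch over the two phase alignments."""
    for hi in [(0, 0), (0, 1), (1, 0), (1, 1)]:
        for hj in [(0, 0), (0, 1), (1, 0), (1, 1)]:
            align1 = (hi[0] != hj[0]) + (hi[1] != hj[1])
            align2 = (hi[0] != hj[1]) + (hi[1] != hj[0])
            expected = (align1 + align2) / 4.0
            assert genotype_difference(sum(hi), sum(hj)) == expected


def test_window_distances_hand_example():
    """(0,1,2) vs (2,1,0) over 100 accessible bases: 1 + 0.5 + 1 = 2.5 diffs."""
    m = tiny_matrix([[0, 2], [1, 1], [2, 0]])
    acc = build_accessibility(None, {"1": 100}, 100)
    wds = window_distances(m, acc)
    assert wds.diff_counts[0, 0, 1] == pytest.approx(2.5)
    assert wds.pair_denominators[0, 0, 1] == 100
    d = aggregate(wds)
    assert d.values[0, 1] == pytest.approx(0.025)


def test_window_without_snps_keeps_full_denominator():
    m = tiny_matrix([[0, 2]], chrom_len=200, window_size=100)
    acc = build_accessibility(None, {"1": 200}, 100)
    wds = window_distances(m, acc)
    assert wds.n_windows == 2
    assert wds.diff_counts[1].sum() == 0.0
    assert wds.pair_denominators[1, 0, 1] == 100


def test_missing_genotype_removed_from_pair_numerator_and_denominator():
    m = tiny_matrix([[0, 2], [-1, 1], [2, 0]])
    acc = build_accessibility(None, {"1": 100}, 100)
    wds = window_distances(m, acc)
    assert wds.diff_counts[0, 0, 1] == pytest.approx(2.0)  # middle site excluded
    assert wds.pair_denominators[0, 0, 1] == 99
    # heterozygosity denominator only drops for the sample with the missing call
    assert wds.het_denominators[0, 0] == 99
    assert wds.het_denominators[0, 1] == 100


def test_site_outside_mask_windows_is_error():
    m = tiny_matrix([[0, 2]], positions=[150], chrom_len=100)
    acc = build_accessibility(None, {"1": 100}, 100)
    with pytest.raises(ValueError, match="outside"):
        window_distances(m, acc)


def test_heterozygosity_hand_values():
    m = tiny_matrix([[0, 0], [1, 0], [1, 2], [2, 0]], chrom_len=1000, window_size=1000)
    acc = build_accessibility(None, {"1": 1000}, 1000)
    wds = window_distances(m, acc)
    het = individual_heterozygosity(wds)
    assert het["s0"] == pytest.approx(2 / 1000)
    assert het["s1"] == pytest.approx(0.0)


def test_aggregate_is_ratio_of_sums():
    m = tiny_matrix([[0, 2], [0, 1], [0, 1], [0, 2]],
                    positions=[1, 2, 101, 102], chrom_len=200, window_size=100)
    acc = build_accessibility(None, {"1": 200}, 100)
    wds = window_distances(m, acc)
    # windows carry (1.5, 100) and (1.5, 100): ratio of sums = 3/200
    d = aggregate(wds)
    assert d.values[0, 1] == pytest.approx(3 / 200)


def test_aggregate_invariant_to_window_partition(small_sim):
    """Ratio-of-sums distances do not depend on the windowing of sites."""
    cfg, matrix, _ = small_sim
    total = cfg.n_windows * cfg.window_size
    fine = window_distances(
        matrix, build_accessibility(None, matrix.chrom_lengths, cfg.window_size)
    )
    coarse = window_distances(
        matrix, build_accessibility(None, matrix.chrom_lengths, total)
    )
    np.testing.assert_allclose(
        aggregate(fine).values, aggregate(coarse).values, atol=1e-15
    )


def test_aggregate_matches_per_base_oracle(small_sim):
    """Windowed sums equal a direct site-by-site computation without windows."""
    cfg, matrix, _ = small_sim
    wds = window_distances(
        matrix, build_accessibility(None, matrix.chrom_lengths, cfg.window_size)
    )
    d = aggregate(wds)
    g = matrix.genotypes
    n = matrix.n_samples
    total_bases = cfg.n_windows * cfg.window_size
    for i in range(0, n, 3):
        for j in range(i + 1, n, 3):
            ok = (g[:, i] >= 0) & (g[:, j] >= 0)
            diffs = sum(
                genotype_difference(int(a), int(b))
                for a, b in zip(g[ok, i], g[ok, j])
            )
            denom = total_bases - int((~ok).sum())
            assert d.values[i, j] == pytest.approx(diffs / denom, rel=1e-12)


def test_phased_oracle_equivalence(small_sim):
    """Genotype-formula distances equal phase-aware averaging exactly."""
    cfg, matrix, _ = small_sim
    hap = matrix.phased_haplotypes
    wds = window_distances(
        matrix, build_accessibility(None, matrix.chrom_lengths, cfg.window_size)
    )
    d = aggregate(wds)
    total_bases = cfg.n_windows * cfg.window_size
    for i, j in [(0, 1), (2, 9), (4, 10)]:
        h_i, h_j = hap[:, i, :], hap[:, j, :]
        # mean over the two phase alignments of per-haplotype mismatches
        a1 = (h_i[:, 0] != h_j[:, 0]).sum() + (h_i[:, 1] != h_j[:, 1]).sum()
        a2 = (h_i[:, 0] != h_j[:, 1]).sum() + (h_i[:, 1] != h_j[:, 0]).sum()
        assert d.values[i, j] == pytest.approx((a1 + a2) / 4 / total_bases, rel=1e-12)


def test_net_distance_arithmetic():
    from utaka.containers import DistanceMatrix

    raw = DistanceMatrix(["a", "b"], np.array([[0.0, 0.002], [0.002, 0.0]]))
    het = pd.Series([0.001, 0.001], index=["a", "b"])
    net = net_distance(raw, het)
    assert net.values[0, 1] == pytest.approx(0.001)
    zero = net_distance(raw, pd.Series([0.0, 0.0], index=["a", "b"]))
    np.testing.assert_allclose(zero.values, raw.values)


def test_net_distance_label_mismatch_is_error():
    from utaka.containers import DistanceMatrix

    raw = DistanceMatrix(["a", "b"], np.zeros((2, 2)))
    with pytest.raises(ValueError):
        net_distance(raw, pd.Series([0.0, 0.0], index=["a", "x"]))


def test_two_population_expectations():
    """Within ~ 4*Ne*mu, cross ~ 2*mu*(T + 2*Ne), net cross ~ 2*mu*T (3 MC SE)."""
    cfg = GenSimConfig(
        n_per_pop=4, n_outgroup=1, ne=10_000, t_split=30_000,
        t_outgroup=300_000, n_windows=250, seed=17,
    )
    matrix, _ = simulate_split_genotypes(cfg)
    wds = window_distances(
        matrix, build_accessibility(None, matrix.chrom_lengths, cfg.window_size)
    )
    ia = [k for k, s in enumerate(matrix.samples) if s.startswith("A")]
    ib = [k for k, s in enumerate(matrix.samples) if s.startswith("B")]

    # per-window mean cross distance gives a Monte-Carlo standard error
    per_win = wds.diff_counts[:, ia][:, :, ib].mean(axis=(1, 2)) / cfg.window_size
    se = per_win.std(ddof=1) / np.sqrt(len(per_win))
    cross = per_win.mean()
    assert abs(cross - 2 * cfg.mu * (cfg.t_split + 2 * cfg.ne)) < 3 * se

    within = wds.diff_counts[:, ia][:, :, ia].sum(axis=(1, 2)) / (
        len(ia) * (len(ia) - 1)
    ) / cfg.window_size
    se_w = within.std(ddof=1) / np.sqrt(len(within))
    assert abs(within.mean() - 4 * cfg.ne * cfg.mu) < 3 * se_w

    het = individual_heterozygosity(wds)
    net = net_distance(aggregate(wds), het)
    net_cross = net.values[np.ix_(ia, ib)].mean()
    assert abs(net_cross - 2 * cfg.mu * cfg.t_split) < 3 * se


def test_net_distance_vanishes_within_population():
    """E[dxy] = E[het] inside one panmictic population."""
    cfg = GenSimConfig(
        n_per_pop=6, n_outgroup=1, ne=10_000, t_split=0.001,
        t_outgroup=100_000, n_windows=200, seed=19,
    )
    matrix, _ = simulate_split_genotypes(cfg)
    wds = window_distances(
        matrix, build_accessibility(None, matrix.chrom_lengths, cfg.window_size)
    )
    net = net_distance(aggregate(wds), individual_heterozygosity(wds))
    ingroup = [k for k, s in enumerate(matrix.samples) if not s.startswith("OUT")]
    vals = net.values[np.ix_(ingroup, ingroup)]
    off = vals[~np.eye(len(ingroup), dtype=bool)]
    assert abs(off.mean()) < 1.5e-5  # ~10% of the 4*Ne*mu diversity scale
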