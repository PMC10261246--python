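"""Synthetic genotype and landmark data with known ground truth.

Genotypes come from a two-population-plus-outgroup structured coalescent:
within each population, lineage pairs coalesce at rate k(k-1)/2 per 2*Ne
generations (continuous-time exponential waiting times); populations A and B
merge into a common ancestral population (size Ne) at ``t_split`` and the
outgroup joins at ``t_outgroup``. Windows are independent, with no
recombination inside a window, and mutations fall on branches as a Poisson
process with rate mu per bp per generation under infinite sites (each
mutation gets a distinct position within the window). Haplotypes are paired
into diploids and the phase is retained.

Site annotations are drawn clean — constant depth, high mapping quality,
balanced strand summaries, zero inbreeding coefficient — so no site-level
masking rule triggers unless violations are planted explicitly with
:func:`plant_filter_violations`. The one realistic noise source kept on is
the per-genotype allele depth of heterozygotes, drawn Binomial(depth, 1/2),
which exercises the allele-balance rule at a realistically small rate.

Landmark sets come from two template mean shapes: per specimen, isotropic
Gaussian noise is added to the group template and an arbitrary similarity
transform (rotation, translation, scale) is applied, the scale being
recorded as the TPS scale factor.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from utaka.containers import SITE_COLUMNS, GenotypeMatrix
from utaka.morphometrics import LandmarkConfiguration


@dataclass
class GenSimConfig:
    """Two-population + outgroup coalescent parameters.

    Defaults match the desk-scale study design: 10 diploids per ingroup
    population and a single outgroup diploid, Ne = 10,000 everywhere, an
    ingroup split 50,000 generations ago, an outgroup split 500,000
    generations ago, mu = 3.5e-9 per bp per generation, and 50 independent
    100-kb windows.
    """

    n_per_pop: int = 10
    n_outgroup: int = 1
    ne: float = 10_000.0
    t_split: float = 50_000.0
    t_outgroup: float = 500_000.0
    mu: float = 3.5e-9
    n_windows: int = 50
    window_size: int = 100_000
    depth_per_sample: int = 20
    seed: int = 0

    def validate(self) -> None:
        if not (self.t_outgroup > self.t_split >= 0):
            raise ValueError("require t_outgroup > t_split >= 0")
        if min(self.n_per_pop, self.n_outgroup, self.n_windows, self.window_size) < 1:
            raise ValueError("counts and sizes must be positive")
        if self.ne <= 0 or self.mu <= 0:
            raise ValueError("ne and mu must be positive")


@dataclass
class ShapeSimConfig:
    """Two-group landmark simulator parameters (defaults: 15-landmark fish)."""

    k: int = 15
    template_a: np.ndarray | None = None
    template_b: np.ndarray | None = None
    noise_sd: float = 0.01
    n_per_group: int = 20
    rotation_range: tuple[float, float] = (-np.pi, np.pi)
    translation_range: tuple[float, float] = (-10.0, 10.0)
    log_scale_range: tuple[float, float] = (np.log(0.5), np.log(2.0))
    seed: int = 0

    def validate(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.n_per_group < 1:
            raise ValueError("n_per_group must be positive")


@dataclass
class SimTruth:
    """Ground-truth parameters carried alongside simulated data."""

    t_split: float | None = None
    t_outgroup: float | None = None
    ne: float | None = None
    mu: float | None = None
    sample_pops: dict[str, str] = field(default_factory=dict)
    mean_shapes: tuple[np.ndarray, np.ndarray] | None = None
    groups: list[str] = field(default_factory=list)
    noise_sd: float | None = None


# -- structured coalescent ----------------------------------------------------


def _simulate_window_tree(
    rng: np.random.Generator, n_hap: dict[str, int], ne: float,
    t_split: float, t_outgroup: float,
):
    """One window genealogy; returns (parent, times, masks) arrays/lists."""
    total = sum(n_hap.values())
    times = [0.0] * total
    parent = [-1] * total
    masks = [1 << i for i in range(total)]

    ids = iter(range(total))
    pools: dict[str, list[int]] = {}
    for pop, cnt in n_hap.items():
        pools[pop] = [next(ids) for _ in range(cnt)]

    stage = 0  # 0: {A, B, O}; 1: {AB, O}; 2: {ABO}
    boundaries = [t_split, t_outgroup]
    t = 0.0
    n_live = total
    while n_live > 1:
        rates = {p: len(v) * (len(v) - 1) / 2.0 / (2.0 * ne) for p, v in pools.items()}
        rate = sum(rates.values())
        if rate == 0.0:
            t = boundaries[stage]
            stage = _advance_stage(pools, stage)
            continue
        dt = rng.exponential(1.0 / rate)
        if stage < 2 and t + dt >= boundaries[stage]:
            t = boundaries[stage]
            stage = _advance_stage(pools, stage)
            continue
        t += dt
        r = rng.random() * rate
        acc = 0.0
        for pop, pr in rates.items():
            acc += pr
            if r < acc or pop == list(rates)[-1]:
                break
        pool = pools[pop]
        i = int(rng.integers(len(pool)))
        j = int(rng.integers(len(pool) - 1))
        if j >= i:
            j += 1
        a, b = pool[i], pool[j]
        node = len(times)
        times.append(t)
        parent.append(-1)
        parent[a] = node
        parent[b] = node
        masks.append(masks[a] | masks[b])
        pool[:] = [x for k, x in enumerate(pool) if k not in (i, j)] + [node]
        n_live -= 1
    return np.asarray(parent), np.asarray(times), masks


def _advance_stage(pools: dict[str, list[int]], stage: int) -> int:
    if stage == 0:
        pools["AB"] = pools.pop("A") + pools.pop("B")
    else:
        pools["ABO"] = pools.pop("AB") + pools.pop("O")
    return stage + 1


def simulate_split_genotypes(
    config: GenSimConfig | None = None,
) -> tuple[GenotypeMatrix, SimTruth]:
    """Simulate a filtered-quality genotype matrix under the split model.

    Sample names are ``A01..``, ``B01..`` and ``OUT1..``; all windows lie on
    one chromosome (``"1"``) and every base is accessible. Deterministic per
    seed.
    """
    config = config or GenSimConfig()
    config.validate()
    rng = np.random.default_rng(config.seed)
    n_hap = {
        "A": 2 * config.n_per_pop,
        "B": 2 * config.n_per_pop,
        "O": 2 * config.n_outgroup,
    }
    width = len(str(config.n_per_pop))
    samples = (
        [f"A{i + 1:0{width}d}" for i in range(config.n_per_pop)]
        + [f"B{i + 1:0{width}d}" for i in range(config.n_per_pop)]
        + [f"OUT{i + 1}" for i in range(config.n_outgroup)]
    )
    n_samples = len(samples)
    n_hap_total = sum(n_hap.values())
    L = config.window_size

    pos_all: list[np.ndarray] = []
    hap_all: list[np.ndarray] = []
    for w in range(config.n_windows):
        parent, times, masks = _simulate_window_tree(
            rng, n_hap, config.ne, config.t_split, config.t_outgroup
        )
        has_parent = parent >= 0
        lengths = np.where(has_parent, times[np.maximum(parent, 0)] - times, 0.0)
        counts = rng.poisson(config.mu * L * lengths)
        m = int(counts.sum())
        if m == 0:
            continue
        # infinite sites within the window: distinct positions
        local = np.sort(rng.choice(L, size=min(m, L), replace=False))
        carriers = np.repeat(np.arange(len(masks)), counts)[: len(local)]
        if n_hap_total <= 63:
            mask_vals = np.asarray([masks[c] for c in carriers], dtype=np.uint64)
            bit = np.arange(n_hap_total, dtype=np.uint64)
            H = ((mask_vals[:, None] >> bit[None, :]) & np.uint64(1)).astype(np.int8)
        else:  # arbitrary sample counts: python-int bit masks
            H = np.zeros((len(local), n_hap_total), dtype=np.int8)
            for r, c in enumerate(carriers):
                mv = masks[c]
                H[r] = [(mv >> b) & 1 for b in range(n_hap_total)]
        pos_all.append(w * L + local + 1)  # 1-based VCF positions
        hap_all.append(H)

    if pos_all:
        pos = np.concatenate(pos_all)
        H = np.vstack(hap_all)
    else:
        pos = np.zeros(0, dtype=int)
        H = np.zeros((0, n_hap_total), dtype=np.int8)
    n_sites = len(pos)
    phased = H.reshape(n_sites, n_samples, 2)
    genotypes = phased.sum(axis=2).astype(np.int8)

    # clean annotations: nothing should trip the site-level masking rules
    d = config.depth_per_sample
    dp_total = d * n_samples
    sites = pd.DataFrame(
        {
            "chrom": "1",
            "pos": pos,
            "ref": "A",
            "alt": "T",
            "total_depth": float(dp_total),
            "mq": 60.0,
            "mq0_fraction": 0.0,
            "fwd_mq_mean": 60.0,
            "fwd_mq_sd": 2.0,
            "fwd_n": float(dp_total // 2),
            "rev_mq_mean": 60.0,
            "rev_mq_sd": 2.0,
            "rev_n": float(dp_total // 2),
            "inbreeding_coeff": 0.0,
        },
        columns=SITE_COLUMNS,
    )

    ad = np.zeros((n_sites, n_samples, 2), dtype=np.int32)
    ad[genotypes == 0, 0] = d
    ad[genotypes == 2, 1] = d
    het = genotypes == 1
    if het.any():
        ref_reads = rng.binomial(d, 0.5, size=int(het.sum()))
        ad[het, 0] = ref_reads
        ad[het, 1] = d - ref_reads

    matrix = GenotypeMatrix(
        samples=samples,
        sites=sites,
        genotypes=genotypes,
        allele_depths=ad,
        phased_haplotypes=phased,
        chrom_lengths={"1": config.n_windows * L},
    )
    truth = SimTruth(
        t_split=config.t_split,
        t_outgroup=config.t_outgroup,
        ne=config.ne,
        mu=config.mu,
        sample_pops={
            s: ("A" if s.startswith("A") else "B" if s.startswith("B") else "O")
            for s in samples
        },
    )
    return matrix, truth


# -- planted filter violations ------------------------------------------------


def plant_filter_violations(
    matrix: GenotypeMatrix, spec: dict[str, int], seed: int = 0
) -> tuple[GenotypeMatrix, dict[str, int]]:
    """Overwrite annotations at random sites so each violates exactly one rule.

    ``spec`` maps rule names (see :data:`utaka.filtering.RULE_NAMES`) to the
    number of sites (or, for ``allele_balance``, genotypes) to corrupt.
    Returns the modified matrix and the planted ledger.
    """
    from utaka.filtering import RULE_NAMES

    unknown = set(spec) - set(RULE_NAMES)
    if unknown:
        raise ValueError(f"unknown rules {sorted(unknown)}")
    total = sum(spec.values())
    if total > matrix.n_sites:
        raise ValueError("requested more violations than available sites")

    rng = np.random.default_rng(seed)
    out = matrix.subset_sites(np.ones(matrix.n_sites, dtype=bool))
    out.allele_depths = matrix.allele_depths.copy() if matrix.allele_depths is not None else None
    out.phased_haplotypes = None  # planting genotype edits invalidates phase
    chosen = rng.choice(matrix.n_sites, size=total, replace=False)
    cursor = 0
    sites = out.sites
    n_missing_needed = int(np.floor(0.20 * matrix.n_samples)) + 1
    if spec.get("missingness", 0) and n_missing_needed >= matrix.n_samples:
        raise ValueError("too few samples to plant a missingness violation")

    for rule, count in spec.items():
        idx = chosen[cursor:cursor + count]
        cursor += count
        if rule == "mq0_fraction":
            sites.loc[idx, "mq0_fraction"] = 0.2
        elif rule == "low_mq":
            sites.loc[idx, "mq"] = 30.0
        elif rule == "strand_mq_bias":
            sites.loc[idx, ["fwd_mq_mean", "fwd_mq_sd", "fwd_n"]] = (60.0, 1.0, 200.0)
            sites.loc[idx, ["rev_mq_mean", "rev_mq_sd", "rev_n"]] = (20.0, 1.0, 200.0)
        elif rule == "depth_percentile":
            sites.loc[idx, "total_depth"] = sites["total_depth"].median() * 10.0
        elif rule == "excess_heterozygosity":
            sites.loc[idx, "inbreeding_coeff"] = -0.9
        elif rule == "allele_balance":
            if out.allele_depths is None:
                raise ValueError("cannot plant allele-balance violations without AD")
            cols = rng.integers(0, matrix.n_samples, size=count)
            out.genotypes[idx, cols] = 1
            out.allele_depths[idx, cols] = (0, 30)
        elif rule == "missingness":
            for i in idx:
                cols = rng.choice(matrix.n_samples, size=n_missing_needed, replace=False)
                out.genotypes[i, cols] = -1
                if out.allele_depths is not None:
                    out.allele_depths[i, cols] = (-1, -1)
    return out, dict(spec)


# -- landmark simulator -------------------------------------------------------

# stylised lateral fish body: 15 fixed anatomical points (snout, eye margins,
# fin insertions, opercular region), coordinates in arbitrary shape units
FISH_TEMPLATE = np.array(
    [
        (0.00, 0.10),  # anterior tip of upper maxilla
        (0.18, 0.16),  # posterior reach of eye
        (0.08, 0.15),  # anterior reach of eye
        (0.13, 0.11),  # ventral reach of eye
        (0.13, 0.20),  # dorsal reach of eye
        (0.35, 0.28),  # anterior insertion of dorsal fin
        (0.78, 0.22),  # posterior insertion of dorsal fin
        (0.80, 0.02),  # posterior insertion of anal fin
        (0.62, 0.00),  # anterior insertion of anal fin
        (0.38, 0.02),  # pelvic fin insertion
        (0.30, 0.06),  # ventral insertion of pectoral fin
        (0.30, 0.12),  # dorsal insertion of pectoral fin
        (0.26, 0.18),  # lateral line meets operculum
        (0.20, 0.04),  # ventral-posterior extreme of preoperculum
        (0.04, 0.14),  # anterior reach of premaxillary groove
    ]
)

# unit "body depth" deformation: dorsal profile up, ventral profile down
_DEPTH_AXIS = np.zeros_like(FISH_TEMPLATE)
_DEPTH_AXIS[[5, 6], 1] = 1.0
_DEPTH_AXIS[[7, 8, 9, 13], 1] = -1.0
_DEPTH_AXIS /= np.sqrt((_DEPTH_AXIS**2).sum())


def default_templates(effect: float = 0.08) -> tuple[np.ndarray, np.ndarray]:
    """Slender (A) and deeper-bodied (B) fish templates, ``effect`` apart."""
    return FISH_TEMPLATE.copy(), FISH_TEMPLATE + effect * _DEPTH_AXIS


def simulate_landmark_sets(
    config: ShapeSimConfig | None = None,
) -> tuple[list[LandmarkConfiguration], SimTruth]:
    """Two groups of noisy landmark configurations under similarity nuisance.

    Specimen ids are ``A_01..`` / ``B_01..``. Deterministic per seed.
    """
    config = config or ShapeSimConfig()
    config.validate()
    ta = config.template_a
    tb = config.template_b
    if ta is None or tb is None:
        da, db = default_templates()
        ta = da if ta is None else np.asarray(ta, float)
        tb = db if tb is None else np.asarray(tb, float)
    ta, tb = np.asarray(ta, float), np.asarray(tb, float)
    if ta.shape != tb.shape or ta.shape[0] != config.k:
        raise ValueError("templates must both be (k, 2)")

    rng = np.random.default_rng(config.seed)
    configs: list[LandmarkConfiguration] = []
    groups: list[str] = []
    for group, template in (("A", ta), ("B", tb)):
        for i in range(config.n_per_group):
            pts = template + rng.normal(0.0, config.noise_sd, size=template.shape)
            theta = rng.uniform(*config.rotation_range)
            scale = float(np.exp(rng.uniform(*config.log_scale_range)))
            shift = rng.uniform(*config.translation_range, size=2)
            rot = np.array(
                [[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]]
            )
            transformed = scale * (pts @ rot.T) + shift
            configs.append(
                LandmarkConfiguration(
                    specimen_id=f"{group}_{i + 1:02d}",
                    landmarks=transformed,
                    scale=scale,
                )
            )
            groups.append(group)
    truth = SimTruth(mean_shapes=(ta, tb), groups=groups, noise_sd=config.noise_sd)
    return configs, truth
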