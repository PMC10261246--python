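"""End-to-end orchestration: filter -> distances -> trees -> dating (+ GM).

`run_full_analysis` executes the whole workflow from a single declarative
config and writes every intermediate artifact plus a manifest recording the
package version, a hash of the configuration, all seeds, and a checksum per
output file. Re-running with the same config and seed reproduces every
artifact bit-identically.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

import utaka
from utaka.containers import GenotypeMatrix
from utaka.dating import DatingConfig, estimate_split_time
from utaka.distances import (
    aggregate,
    individual_heterozygosity,
    net_distance,
    window_distances,
)
from utaka.filtering import FilterConfig, build_accessibility, site_masks
from utaka.trees import (
    block_bootstrap_support,
    local_tree_support_fraction,
    neighbor_joining,
    nj_input,
    root_by_outgroup,
)
from utaka.containers import DistanceMatrix
from utaka.vcfio import load_biallelic_snps


@dataclass
class RunConfig:
    """Declarative configuration for a full run."""

    vcf: str
    out_dir: str
    outgroup: str
    group_a: list[str]
    group_b: list[str]
    mask: str | None = None
    tps: str | None = None
    filter: FilterConfig = field(default_factory=FilterConfig)
    dating: DatingConfig = field(default_factory=DatingConfig)
    bootstrap_replicates: int = 1000
    seed: int = 0
    local_trees: bool = True

    def validate(self) -> None:
        if set(self.group_a) & set(self.group_b):
            raise ValueError("groups must be disjoint")
        if self.outgroup in set(self.group_a) | set(self.group_b):
            raise ValueError("outgroup must not be in either group")
        if not os.path.exists(self.vcf):
            raise FileNotFoundError(self.vcf)
        for p in (self.mask, self.tps):
            if p is not None and not os.path.exists(p):
                raise FileNotFoundError(p)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def _sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def run_full_analysis(config: RunConfig) -> dict:
    """Run every stage in order and return the manifest (also written as JSON)."""
    config.validate()
    os.makedirs(config.out_dir, exist_ok=True)
    artifacts: dict[str, str] = {}

    def emit(name: str, path: str) -> None:
        artifacts[name] = path

    def stage(name: str):
        class _Ctx:
            def __enter__(self):
                return None

            def __exit__(self, exc_type, exc, tb):
                if exc is not None:
                    raise StageError(name, exc) from exc
                return False

        return _Ctx()

    out = config.out_dir

    with stage("load"):
        matrix = load_biallelic_snps(config.vcf)

    with stage("filter"):
        filtered, report = site_masks(matrix, config.filter)
        p = os.path.join(out, "filter_report.tsv")
        report.to_frame().to_csv(p, sep="\t", index=False)
        emit("filter_report", p)
        p = os.path.join(out, "filter.log")
        with open(p, "w") as fh:
            fh.write("\n".join(report.log_lines()) + "\n")
        emit("filter_log", p)

    with stage("accessibility"):
        acc = build_accessibility(
            config.mask, matrix.chrom_lengths, config.filter.window_size
        )
        p = os.path.join(out, "accessibility.tsv")
        acc.to_tsv(p)
        emit("accessibility", p)

    with stage("distances"):
        wds = window_distances(filtered, acc)
        p = os.path.join(out, "window_distances.tsv")
        wds.to_long_frame().to_csv(p, sep="\t", index=False)
        emit("window_distances", p)
        raw = aggregate(wds)
        het = individual_heterozygosity(wds)
        net = net_distance(raw, het)
        for name, dm in (("raw_distances", raw), ("net_distances", net)):
            p = os.path.join(out, f"{name}.tsv")
            dm.to_tsv(p)
            emit(name, p)
            p = os.path.join(out, f"{name}.phy")
            dm.to_phylip(p)
            emit(name + "_phylip", p)
        p = os.path.join(out, "heterozygosity.tsv")
        het.to_csv(p, sep="\t")
        emit("heterozygosity", p)

    with stage("trees"):
        coal_tree = root_by_outgroup(neighbor_joining(raw), config.outgroup)
        clamped, n_neg = nj_input(net.values)
        split_tree = root_by_outgroup(
            neighbor_joining(DistanceMatrix(net.labels, clamped)), config.outgroup
        )
        p = os.path.join(out, "coalescent_tree.nwk")
        with open(p, "w") as fh:
            fh.write(coal_tree.to_newick() + "\n")
        emit("coalescent_tree", p)
        p = os.path.join(out, "split_tree.nwk")
        with open(p, "w") as fh:
            fh.write(split_tree.to_newick() + "\n")
        emit("split_tree", p)

    with stage("bootstrap"):
        target = set(config.group_a)
        results = block_bootstrap_support(
            wds,
            bipartitions=[target],
            replicates=config.bootstrap_replicates,
            seed=config.seed,
            net=True,
        )
        rows = [
            (
                "|".join(sorted(r.bipartition)),
                r.support,
                r.replicates,
                r.seed,
                r.rejected_replicates,
            )
            for r in results
        ]
        p = os.path.join(out, "bootstrap_supports.tsv")
        pd.DataFrame(
            rows, columns=["bipartition", "support", "replicates", "seed", "rejected"]
        ).to_csv(p, sep="\t", index=False)
        emit("bootstrap_supports", p)

    with stage("dating"):
        est = estimate_split_time(
            split_tree, set(config.group_a), set(config.group_b), config.dating
        )
        p = os.path.join(out, "split_time.json")
        with open(p, "w") as fh:
            json.dump(
                {
                    "node_height": est.node_height,
                    "mu": config.dating.mu,
                    "mu_ci": list(config.dating.mu_ci),
                    "generation_time": config.dating.generation_time,
                    "t_years": est.t_years,
                    "ci_years": list(est.ci_years),
                },
                fh,
                indent=2,
            )
            fh.write("\n")
        emit("split_time", p)

    if config.local_trees:
        with stage("local_trees"):
            frac = local_tree_support_fraction(
                wds, set(config.group_a), set(config.group_b)
            )
            p = os.path.join(out, "local_tree_support.json")
            with open(p, "w") as fh:
                json.dump({"support_fraction": frac}, fh, indent=2)
                fh.write("\n")
            emit("local_tree_support", p)

    if config.tps is not None:
        with stage("morphometrics"):
            from utaka.morphometrics import procrustes_align, read_tps, shape_pca

            configs = read_tps(config.tps)
            aligned = procrustes_align(configs)
            pca = shape_pca(aligned)
            n, k, _ = aligned.coords.shape
            flat = pd.DataFrame(
                aligned.coords.reshape(n, -1),
                index=aligned.specimen_ids,
                columns=[f"{ax}{i + 1}" for i in range(k) for ax in ("x", "y")],
            )
            p = os.path.join(out, "aligned_coords.tsv")
            flat.to_csv(p, sep="\t")
            emit("aligned_coords", p)
            p = os.path.join(out, "shape_eigenvalues.tsv")
            pd.DataFrame(
                {
                    "eigenvalue": pca.eigenvalues,
                    "percent_variance": pca.percent_variance,
                }
            ).to_csv(p, sep="\t", index_label="component")
            emit("shape_eigenvalues", p)
            p = os.path.join(out, "shape_scores.tsv")
            pd.DataFrame(
                pca.scores,
                index=aligned.specimen_ids,
                columns=[f"PC{i + 1}" for i in range(pca.scores.shape[1])],
            ).to_csv(p, sep="\t")
            emit("shape_scores", p)
            p = os.path.join(out, "centroid_sizes.tsv")
            pd.Series(
                aligned.centroid_sizes, index=aligned.specimen_ids, name="centroid_size"
            ).to_csv(p, sep="\t")
            emit("centroid_sizes", p)

    config_json = json.dumps(config.to_dict(), sort_keys=True, default=str)
    manifest = {
        "package_version": utaka.__version__,
        "config_hash": hashlib.sha256(config_json.encode()).hexdigest(),
        "seed": config.seed,
        "artifacts": {
            name: {"path": path, "sha256": _sha256(path)}
            for name, path in artifacts.items()
        },
    }
    p = os.path.join(out, "manifest.json")
    with open(p, "w") as fh:
        json.dump(manifest, fh, indent=2)
        fh.write("\n")
    return manifest
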