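"""End-to-end orchestration: CMF -> screening -> statistics from one config.

One config-driven run writes every intermediate artifact (CMF table,
presence matrix, adherence report, distance matrices, ordination scores,
linkage) plus a machine-readable JSON summary, so each reported number has
a corresponding file.  Re-running with an identical config and seed
reproduces the summary bit for bit.
"""

from __future__ import annotations

import hashlib
import json
import logging
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .annotation_io import (
    SourceGroup,
    read_annotation,
    read_quality_table,
    write_presence_matrix,
)
from .cmf_builder import (
    DEFAULT_UNCERTAINTY_MARKERS,
    CMFSet,
    assign_functional_categories,
    build_cmf,
    read_category_map,
    read_cmf_table,
    write_cmf_table,
)
from .group_stats import kendall_tau_b, kruskal_wallis, rank_sum_test, fisher_exact_2x2
from .ordination_clustering import (
    cluster_source_table,
    distance_matrix,
    logistic_pca,
    pca_binary,
    permanova,
    ward_cluster,
)
from .screening import adherence_report, build_presence_matrix, count_above, missing_profile

__all__ = ["AnalysisConfig", "PipelineError", "run_full_analysis"]

logger = logging.getLogger("cmfscan")


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass
class AnalysisConfig:
    """All paths and parameters of one full analysis run."""

    genome_dir: str
    groups_path: str
    output_dir: str
    cmf_path: str | None = None
    reference_genome_paths: list[str] = field(default_factory=list)
    quality_path: str | None = None
    category_map_path: str | None = None
    uncertainty_markers: list[str] = field(
        default_factory=lambda: list(DEFAULT_UNCERTAINTY_MARKERS)
    )
    exclusion_list: list[str] = field(default_factory=list)
    metric: str = "jaccard_binary"
    n_permutations: int = 999
    seed: int = 17
    quality_threshold: float = 90.0
    missingness_threshold: float = 50.0
    run_logistic_pca: bool = False
    logistic_rank: int = 2

    def __post_init__(self) -> None:
        if self.cmf_path is None and not self.reference_genome_paths:
            raise ValueError(
                "config needs either cmf_path or reference_genome_paths"
            )
        if self.seed is None:
            raise ValueError("a seed is required (stochastic stages are enabled)")

    @classmethod
    def from_json(cls, path: str | Path) -> "AnalysisConfig":
        with open(path, encoding="utf-8") as fh:
            return cls(**json.load(fh))

    def canonical_json(self) -> str:
        return json.dumps(asdict(self), sort_keys=True)

    def config_hash(self) -> str:
        return hashlib.sha256(self.canonical_json().encode()).hexdigest()[:16]


def _stage(name: str):
    def deco(fn):
        def wrapped(*args, **kwargs):
            logger.info("stage %s: start", name)
            try:
                out = fn(*args, **kwargs)
            except Exception as exc:
                raise PipelineError(f"stage {name!r} failed: {exc}") from exc
            logger.info("stage %s: done", name)
            return out

        return wrapped

    return deco


@_stage("load_cmf")
def _load_cmf(config: AnalysisConfig) -> CMFSet:
    if config.cmf_path:
        cmf = read_cmf_table(config.cmf_path)
    else:
        refs = [
            read_annotation(p, Path(p).stem, SourceGroup.OTHER)
            for p in config.reference_genome_paths
        ]
        cmf = build_cmf(
            refs,
            require_all=True,
            uncertainty_markers=config.uncertainty_markers,
            exclusion_list=config.exclusion_list,
        )
    if config.category_map_path:
        cmf = assign_functional_categories(cmf, read_category_map(config.category_map_path))
    return cmf


@_stage("read_genomes")
def _read_genomes(config: AnalysisConfig):
    groups = pd.read_csv(config.groups_path, sep="\t")
    if "genome_id" not in groups.columns or "source_group" not in groups.columns:
        raise ValueError("groups table needs genome_id and source_group columns")
    genome_dir = Path(config.genome_dir)
    annotations = []
    for row in groups.itertuples(index=False):
        path = None
        for ext in (".gff", ".gff3", ".tsv"):
            cand = genome_dir / f"{row.genome_id}{ext}"
            if cand.exists():
                path = cand
                break
        if path is None:
            raise FileNotFoundError(
                f"no annotation file for genome {row.genome_id!r} in {genome_dir}"
            )
        annotations.append(
            read_annotation(path, str(row.genome_id), SourceGroup(row.source_group))
        )
    return annotations


def run_full_analysis(config: AnalysisConfig) -> dict:
    """Run CMF loading/derivation, screening and all statistics.

    Returns the analysis summary (also written as ``summary.json``): CMF
    size, per-group adherence mean/SD, missingness counts, every test
    result, the PERMANOVA outcome, ordination variance fractions and full
    provenance.  With fewer than two source groups the comparison stages
    are skipped with a warning; screening artifacts are still produced.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)

    cmf = _load_cmf(config)
    write_cmf_table(cmf, out / "cmf.tsv")

    annotations = _read_genomes(config)
    quality = read_quality_table(config.quality_path) if config.quality_path else None

    matrix = build_presence_matrix(cmf, annotations)
    write_presence_matrix(matrix, out / "matrix.tsv")
    report = adherence_report(matrix, quality)
    report.table.to_csv(out / "report.tsv", sep="\t", index=False)

    summary: dict = {
        "cmfscan_version": __version__,
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "cmf_size": len(cmf),
        "n_genomes": matrix.n_genomes,
        "groups": {},
        "tests": [],
    }
    for row in report.group_summary().itertuples(index=False):
        summary["groups"][row.source_group] = {
            "n": int(row.n),
            "adherence_mean": round(float(row.mean), 4),
            "adherence_sd": None if np.isnan(row.sd) else round(float(row.sd), 4),
        }

    groups_present = sorted({g.value for g in matrix.source_groups})
    profile_all = missing_profile(matrix)
    profile_all.to_csv(out / "missing_profile.tsv", sep="\t", header=True)
    summary["missing_count_above_threshold"] = {
        "threshold_percent": config.missingness_threshold,
        "all": count_above(profile_all, config.missingness_threshold),
    }
    for g in groups_present:
        summary["missing_count_above_threshold"][g] = count_above(
            missing_profile(matrix, g), config.missingness_threshold
        )

    by_group = {
        g: report.table.loc[
            report.table["source_group"] == g, "adherence_percent"
        ].to_numpy()
        for g in groups_present
    }

    if len(groups_present) < 2:
        warnings.warn(
            "fewer than two source groups: comparison statistics skipped",
            stacklevel=2,
        )
        summary["comparisons_skipped"] = True
    else:
        samples = [by_group[g] for g in groups_present]
        summary["tests"].append(kruskal_wallis(samples).to_dict())
        if len(groups_present) == 2:
            summary["tests"].append(
                rank_sum_test(samples[0], samples[1]).to_dict()
            )

        dist = distance_matrix(matrix, config.metric)
        pd.DataFrame(dist.values, index=dist.ids, columns=dist.ids).to_csv(
            out / f"distances_{config.metric}.tsv", sep="\t"
        )
        clustering = ward_cluster(dist, k=2)
        np.savetxt(out / "linkage.tsv", clustering.linkage, delimiter="\t")
        if len(groups_present) == 2:
            table = cluster_source_table(
                clustering.labels(2), [g.value for g in matrix.source_groups]
            )
            fisher = fisher_exact_2x2(table)
            summary["tests"].append(fisher.to_dict())
            summary["cluster_source_table"] = table.tolist()

        ordin = pca_binary(matrix, n_axes=2)
        pd.DataFrame(
            ordin.coordinates, index=ordin.ids, columns=["PC1", "PC2"]
        ).to_csv(out / "pca_scores.tsv", sep="\t")
        summary["pca_explained_variance_fraction"] = [
            round(float(v), 6) for v in ordin.explained_variance_fraction
        ]
        if config.run_logistic_pca:
            lp = logistic_pca(matrix, rank=config.logistic_rank, seed=config.seed)
            pd.DataFrame(
                lp.coordinates,
                index=lp.ids,
                columns=[f"LPC{i + 1}" for i in range(lp.coordinates.shape[1])],
            ).to_csv(out / "logistic_pca_scores.tsv", sep="\t")
            summary["logistic_pca_explained_variance_fraction"] = [
                round(float(v), 6) for v in lp.explained_variance_fraction
            ]

        edist = (
            dist
            if config.metric == "euclidean_binary"
            else distance_matrix(matrix, "euclidean_binary")
        )
        perma = permanova(
            edist,
            [g.value for g in matrix.source_groups],
            n_permutations=config.n_permutations,
            seed=config.seed,
        )
        summary["permanova"] = perma.to_dict()

    if quality is not None:
        with_quality = report.table.dropna(subset=["completeness"])
        if len(with_quality) >= 3:
            tau = kendall_tau_b(
                with_quality["adherence_percent"].to_numpy(),
                with_quality["completeness"].to_numpy(),
            )
            summary["adherence_completeness_kendall"] = tau.to_dict()
        strata = report.quality_strata_summary(config.quality_threshold)
        strata.to_csv(out / "quality_strata.tsv", sep="\t", index=False)
        summary["quality_strata"] = json.loads(strata.to_json(orient="records"))

    with open(out / "summary.json", "w", encoding="utf-8") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
    return summary
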