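"""Screening genomes against a CMF: presence profiles, adherence, missingness.

A genome "adheres" to the reference set to the extent that its annotation
contains the core minimal functions: adherence is the percentage of CMF keys
detected among the genome's normalized gene keys.  Screened genomes are
*not* certainty-filtered — a confidently called gene in a draft genome
counts as present regardless of how the reference filter would treat the
same product string (configurable via ``apply_certainty_filter``).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .annotation_io import GenomeAnnotation, QualityScore, SourceGroup
from .cmf_builder import CMFSet, filter_certain_genes, normalize_key

__all__ = [
    "PresenceMatrix",
    "AdherenceReport",
    "screen_genome",
    "adherence",
    "build_presence_matrix",
    "missing_profile",
    "count_above",
    "adherence_report",
    "HIGH_QUALITY_COMPLETENESS",
]

#: completeness at or above this percent counts as "high quality"
#: (ties go to high quality: "equal or greater").
HIGH_QUALITY_COMPLETENESS = 90.0


@dataclass
class PresenceMatrix:
    """Genomes x CMF-keys binary matrix with per-genome group labels."""

    genome_ids: list[str]
    source_groups: list[SourceGroup]
    cmf_keys: list[str]
    cells: np.ndarray  # shape (n_genomes, n_keys), dtype int8, values {0,1}

    def __post_init__(self) -> None:
        self.cells = np.asarray(self.cells, dtype="int8")
        if self.cells.shape != (len(self.genome_ids), len(self.cmf_keys)):
            raise ValueError(
                f"cells shape {self.cells.shape} inconsistent with "
                f"{len(self.genome_ids)} genomes x {len(self.cmf_keys)} keys"
            )
        if len(self.source_groups) != len(self.genome_ids):
            raise ValueError("source_groups must parallel genome_ids")
        if len(set(self.genome_ids)) != len(self.genome_ids):
            raise ValueError("duplicate genome_id in presence matrix")
        if self.cells.size and not np.isin(self.cells, (0, 1)).all():
            raise ValueError("presence matrix cells must be binary")

    @classmethod
    def empty(cls, cmf_keys: Sequence[str]) -> "PresenceMatrix":
        return cls([], [], list(cmf_keys), np.zeros((0, len(cmf_keys)), dtype="int8"))

    @property
    def n_genomes(self) -> int:
        return len(self.genome_ids)

    @property
    def n_keys(self) -> int:
        return len(self.cmf_keys)

    def group_mask(self, group: SourceGroup | str) -> np.ndarray:
        group = SourceGroup(group)
        return np.array([g == group for g in self.source_groups], dtype=bool)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.cells, columns=self.cmf_keys, index=self.genome_ids)
        df.insert(0, "source_group", [g.value for g in self.source_groups])
        return df


@dataclass
class AdherenceReport:
    """Per-genome adherence percentages joined to quality scores."""

    table: pd.DataFrame  # genome_id, source_group, adherence_percent, n_missing, completeness
    n_cmf: int

    def group_summary(self) -> pd.DataFrame:
        """Mean and sample (n-1) standard deviation of adherence per group."""
        g = self.table.groupby("source_group", sort=True)["adherence_percent"]
        out = g.agg(n="size", mean="mean", sd=lambda s: s.std(ddof=1))
        return out.reset_index()

    def quality_strata_summary(
        self, threshold: float = HIGH_QUALITY_COMPLETENESS
    ) -> pd.DataFrame:
        """Adherence summary per (group, quality stratum).

        Genomes with completeness >= ``threshold`` form the high-quality
        stratum (boundary inclusive); genomes without a completeness score
        are reported in their own stratum.
        """
        t = self.table.copy()
        comp = t["completeness"]
        t["quality_stratum"] = np.where(
            comp.isna(), "unscored", np.where(comp >= threshold, "high", "low")
        )
        g = t.groupby(["source_group", "quality_stratum"], sort=True)["adherence_percent"]
        return g.agg(n="size", mean="mean", sd=lambda s: s.std(ddof=1)).reset_index()


# ---------------------------------------------------------------------------
# screening
# ---------------------------------------------------------------------------

def screen_genome(
    cmf: CMFSet,
    annotation: GenomeAnnotation,
    apply_certainty_filter: bool = False,
) -> np.ndarray:
    """Binary presence vector of the CMF keys in one genome's annotation.

    Position ``j`` is 1 iff any gene record of the genome normalizes to
    ``cmf.keys[j]``.  Duplicated records cannot change the result.
    """
    if len(cmf) == 0:
        raise ValueError("cannot screen against an empty CMF")
    if apply_certainty_filter:
        annotation = filter_certain_genes(annotation)
    observed = {normalize_key(g) for g in annotation.genes}
    return np.fromiter(
        (1 if k in observed else 0 for k in cmf.keys), dtype="int8", count=len(cmf)
    )


def adherence(vector: np.ndarray) -> float:
    """Percent of CMF keys present in a profile, to one decimal."""
    vector = np.asarray(vector)
    if vector.size == 0:
        raise ValueError("adherence of a zero-length profile is undefined")
    return round(100.0 * float(vector.sum()) / vector.size, 1)


def build_presence_matrix(
    cmf: CMFSet,
    annotations: Sequence[GenomeAnnotation],
    apply_certainty_filter: bool = False,
) -> PresenceMatrix:
    """Screen every genome and stack the profiles, rows in input order."""
    if not annotations:
        raise ValueError("no annotations to screen")
    ids = [a.genome_id for a in annotations]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate genome_id among screened annotations")
    cells = np.stack(
        [screen_genome(cmf, a, apply_certainty_filter) for a in annotations]
    )
    return PresenceMatrix(
        genome_ids=ids,
        source_groups=[a.source_group for a in annotations],
        cmf_keys=list(cmf.keys),
        cells=cells,
    )


def missing_profile(
    matrix: PresenceMatrix, group: SourceGroup | str | None = None
) -> pd.Series:
    """Per-key percentage of genomes (of one group, or all) lacking the key."""
    if group is None:
        cells = matrix.cells
    else:
        mask = matrix.group_mask(group)
        if not mask.any():
            raise ValueError(f"no genomes in group {group!r}")
        cells = matrix.cells[mask]
    missing = 100.0 * (cells == 0).mean(axis=0)
    return pd.Series(missing, index=matrix.cmf_keys, name="missing_percent")


def count_above(profile: pd.Series, threshold: float) -> int:
    """Number of CMF keys missing in strictly more than ``threshold`` percent."""
    return int((profile > threshold).sum())


def adherence_report(
    matrix: PresenceMatrix,
    quality: Mapping[str, QualityScore] | None = None,
) -> AdherenceReport:
    """Per-genome adherence and missing-gene counts, joined to completeness.

    Genomes absent from the quality mapping get an empty completeness and
    a warning; group summaries use the sample (n-1) standard deviation.
    """
    if matrix.n_genomes == 0:
        raise ValueError("presence matrix has no genomes")
    present = matrix.cells.sum(axis=1)
    n = matrix.n_keys
    completeness = np.full(matrix.n_genomes, np.nan)
    if quality is not None:
        unmatched = [g for g in matrix.genome_ids if g not in quality]
        if unmatched:
            warnings.warn(
                f"{len(unmatched)} genome(s) missing from quality table "
                f"(first: {unmatched[0]!r}); completeness left empty",
                stacklevel=2,
            )
        completeness = np.array(
            [
                quality[g].completeness if g in quality else np.nan
                for g in matrix.genome_ids
            ]
        )
    table = pd.DataFrame(
        {
            "genome_id": matrix.genome_ids,
            "source_group": [g.value for g in matrix.source_groups],
            "adherence_percent": np.round(100.0 * present / n, 1),
            "n_missing": (n - present).astype(int),
            "completeness": completeness,
        }
    )
    return AdherenceReport(table=table, n_cmf=n)
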