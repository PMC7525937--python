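"""Readers and writers for annotated genomes, quality tables and matrices.

Genome annotations come in as either GFF3 (the dialect emitted by standard
prokaryotic annotators: nine tab-separated columns, ``key=value`` attribute
pairs, optional trailing ``##FASTA`` section) or as the seven-column
tab-separated feature table the same annotators produce alongside it.
Only gene-level features are retained — coordinates and sequence are
irrelevant to presence/absence screening and are discarded on read.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import TYPE_CHECKING, Mapping
from urllib.parse import unquote

import pandas as pd

if TYPE_CHECKING:  # pragma: no cover
    from .screening import PresenceMatrix

__all__ = [
    "FeatureType",
    "SourceGroup",
    "GeneRecord",
    "QualityScore",
    "GenomeAnnotation",
    "AnnotationParseError",
    "read_annotation",
    "read_quality_table",
    "write_presence_matrix",
    "read_presence_matrix",
]


class FeatureType(str, Enum):
    """Gene-level feature classes retained from an annotation."""

    CDS = "CDS"
    TRNA = "tRNA"
    RRNA = "rRNA"
    TMRNA = "tmRNA"
    OTHER = "other"

    @classmethod
    def from_string(cls, s: str) -> "FeatureType":
        for ft in (cls.CDS, cls.TRNA, cls.RRNA, cls.TMRNA):
            if s == ft.value:
                return ft
        return cls.OTHER


#: feature types that become :class:`GeneRecord`; everything else
#: (``gene`` parents, ``repeat_region``, ...) is skipped on read.
RETAINED_FEATURE_TYPES = frozenset(
    {FeatureType.CDS, FeatureType.TRNA, FeatureType.RRNA, FeatureType.TMRNA}
)

DEFAULT_PRODUCT = "hypothetical protein"


class SourceGroup(str, Enum):
    """Provenance of a genome: isolate, metagenome-assembled, or simulated."""

    NCBI = "NCBI"
    UMGS = "UMGS"
    SYNTHETIC = "SYNTHETIC"
    OTHER = "OTHER"


class AnnotationParseError(ValueError):
    """Raised when an annotation or table file cannot be parsed."""


@dataclass(frozen=True)
class GeneRecord:
    """One annotated gene-level feature."""

    feature_type: FeatureType
    gene_symbol: str | None
    product: str
    locus_id: str

    def __post_init__(self) -> None:
        if not self.product:
            raise ValueError("GeneRecord.product must be non-empty")
        if not self.locus_id:
            raise ValueError("GeneRecord.locus_id must be non-empty")


@dataclass(frozen=True)
class QualityScore:
    """CheckM-style completeness/contamination estimate, in percent."""

    completeness: float
    contamination: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.completeness <= 100.0:
            raise ValueError(
                f"completeness must be in [0, 100], got {self.completeness}"
            )
        if self.contamination < 0.0:
            raise ValueError(
                f"contamination must be >= 0, got {self.contamination}"
            )


@dataclass
class GenomeAnnotation:
    """All retained gene records of one genome, with provenance."""

    genome_id: str
    source_group: SourceGroup
    genes: list[GeneRecord] = field(default_factory=list)
    quality: QualityScore | None = None

    def __post_init__(self) -> None:
        if not self.genome_id:
            raise ValueError("genome_id must be non-empty")
        seen: set[str] = set()
        for g in self.genes:
            if g.locus_id in seen:
                raise ValueError(
                    f"duplicate locus_id {g.locus_id!r} in genome "
                    f"{self.genome_id!r}"
                )
            seen.add(g.locus_id)

    def __len__(self) -> int:
        return len(self.genes)


# ---------------------------------------------------------------------------
# annotation readers
# ---------------------------------------------------------------------------

def _parse_gff3_attributes(raw: str) -> dict[str, str]:
    attrs: dict[str, str] = {}
    for chunk in raw.split(";"):
        chunk = chunk.strip()
        if not chunk or "=" not in chunk:
            continue
        key, _, value = chunk.partition("=")
        attrs[key.strip()] = unquote(value.strip())
    return attrs


def _read_gff3(path: Path, genome_id: str, source_group: SourceGroup) -> GenomeAnnotation:
    genes: list[GeneRecord] = []
    counter = 0
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if line.startswith("##FASTA"):
                break
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise AnnotationParseError(
                    f"{path}: line {lineno}: expected 9 tab-separated GFF3 "
                    f"columns, found {len(fields)}"
                )
            ftype = FeatureType.from_string(fields[2])
            if ftype not in RETAINED_FEATURE_TYPES:
                continue
            attrs = _parse_gff3_attributes(fields[8])
            counter += 1
            locus = attrs.get("locus_tag") or attrs.get("ID") or f"feature_{counter}"
            product = attrs.get("product") or DEFAULT_PRODUCT
            genes.append(
                GeneRecord(
                    feature_type=ftype,
                    gene_symbol=attrs.get("gene") or None,
                    product=product,
                    locus_id=locus,
                )
            )
    return GenomeAnnotation(genome_id=genome_id, source_group=source_group, genes=genes)


_TABLE_MISSING = {"", "-", "—", "NA", "nan"}


def _read_feature_table(path: Path, genome_id: str, source_group: SourceGroup) -> GenomeAnnotation:
    try:
        df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    except Exception as exc:  # noqa: BLE001 - surface as parse error
        raise AnnotationParseError(f"{path}: cannot parse feature table: {exc}") from exc
    required = {"locus_tag", "ftype", "product"}
    missing = required - set(df.columns)
    if missing:
        raise AnnotationParseError(
            f"{path}: feature table missing column(s) {sorted(missing)}"
        )
    genes: list[GeneRecord] = []
    for row in df.itertuples(index=False):
        ftype = FeatureType.from_string(getattr(row, "ftype"))
        if ftype not in RETAINED_FEATURE_TYPES:
            continue
        symbol = getattr(row, "gene", "") if "gene" in df.columns else ""
        product = getattr(row, "product")
        genes.append(
            GeneRecord(
                feature_type=ftype,
                gene_symbol=None if symbol in _TABLE_MISSING else symbol,
                product=product if product not in _TABLE_MISSING else DEFAULT_PRODUCT,
                locus_id=getattr(row, "locus_tag"),
            )
        )
    return GenomeAnnotation(genome_id=genome_id, source_group=source_group, genes=genes)


def read_annotation(
    path: str | Path,
    genome_id: str,
    source_group: SourceGroup | str = SourceGroup.OTHER,
) -> GenomeAnnotation:
    """Read a genome annotation from GFF3 or a tab-separated feature table.

    The format is auto-detected from the first line: a ``##gff-version``
    directive or a 9-column line selects GFF3, a header naming ``locus_tag``
    and ``ftype`` selects the feature-table dialect.  Features other than
    CDS / tRNA / rRNA / tmRNA are skipped; a CDS without a ``product``
    attribute is recorded as ``"hypothetical protein"``.

    A file with no retained features yields an empty annotation and a
    :class:`UserWarning` (degenerate genomes are allowed but flagged).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    source_group = SourceGroup(source_group)
    with open(path, encoding="utf-8") as fh:
        first = fh.readline().rstrip("\n")
    if first.startswith("##gff-version"):
        ann = _read_gff3(path, genome_id, source_group)
    elif "locus_tag" in first.split("\t") and "ftype" in first.split("\t"):
        ann = _read_feature_table(path, genome_id, source_group)
    elif len(first.split("\t")) == 9:
        ann = _read_gff3(path, genome_id, source_group)
    else:
        raise AnnotationParseError(
            f"{path}: line 1: cannot determine format (neither GFF3 nor a "
            "locus_tag/ftype feature table)"
        )
    if not ann.genes:
        warnings.warn(
            f"{path}: no gene-level features found; returning empty "
            f"annotation for genome {genome_id!r}",
            stacklevel=2,
        )
    return ann


# ---------------------------------------------------------------------------
# quality table
# ---------------------------------------------------------------------------

def read_quality_table(path: str | Path) -> dict[str, QualityScore]:
    """Read a CheckM-style TSV with columns genome_id/completeness/contamination."""
    df = pd.read_csv(path, sep="\t")
    required = {"genome_id", "completeness", "contamination"}
    missing = required - set(df.columns)
    if missing:
        raise AnnotationParseError(
            f"{path}: quality table missing column(s) {sorted(missing)}"
        )
    if df.empty:
        warnings.warn(f"{path}: empty quality table", stacklevel=2)
        return {}
    dup = df["genome_id"][df["genome_id"].duplicated()]
    if not dup.empty:
        raise AnnotationParseError(
            f"{path}: duplicate genome_id(s): {sorted(dup.unique())}"
        )
    out: dict[str, QualityScore] = {}
    for row in df.itertuples(index=False):
        try:
            score = QualityScore(float(row.completeness), float(row.contamination))
        except ValueError as exc:
            raise AnnotationParseError(
                f"{path}: genome {row.genome_id!r}: {exc}"
            ) from exc
        out[str(row.genome_id)] = score
    return out


# ---------------------------------------------------------------------------
# presence/absence matrix round trip
# ---------------------------------------------------------------------------

def write_presence_matrix(matrix: "PresenceMatrix", path: str | Path) -> None:
    """Write a genomes x CMF-keys binary matrix as TSV.

    First column ``genome_id``, second ``source_group``, then one column per
    CMF key in CMF order, with cells written exactly as ``0``/``1`` so the
    write → read round trip is bit-exact.
    """
    if matrix.n_genomes == 0 or matrix.n_keys == 0:
        raise ValueError("cannot write an empty presence matrix")
    df = pd.DataFrame(matrix.cells.astype(int), columns=matrix.cmf_keys)
    df.insert(0, "source_group", [g.value for g in matrix.source_groups])
    df.insert(0, "genome_id", matrix.genome_ids)
    df.to_csv(path, sep="\t", index=False)


def read_presence_matrix(path: str | Path) -> "PresenceMatrix":
    """Read a matrix in the dialect written by :func:`write_presence_matrix`."""
    from .screening import PresenceMatrix

    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if "genome_id" not in df.columns or "source_group" not in df.columns:
        raise AnnotationParseError(
            f"{path}: presence matrix must start with genome_id and source_group"
        )
    keys = [c for c in df.columns if c not in ("genome_id", "source_group")]
    if df.empty:
        warnings.warn(f"{path}: header-only presence matrix", stacklevel=2)
        return PresenceMatrix.empty(keys)
    cells = df[keys].to_numpy()
    bad = (cells != "0") & (cells != "1")
    if bad.any():
        i, j = [int(x[0]) for x in bad.nonzero()]
        raise AnnotationParseError(
            f"{path}: non-binary cell {cells[i, j]!r} at genome "
            f"{df['genome_id'].iloc[i]!r}, key {keys[j]!r}"
        )
    return PresenceMatrix(
        genome_ids=list(df["genome_id"]),
        source_groups=[SourceGroup(g) for g in df["source_group"]],
        cmf_keys=keys,
        cells=cells.astype("int8"),
    )


def write_quality_table(quality: Mapping[str, QualityScore], path: str | Path) -> None:
    """Write a genome_id/completeness/contamination TSV (inverse of the reader)."""
    rows = [
        {"genome_id": gid, "completeness": q.completeness, "contamination": q.contamination}
        for gid, q in quality.items()
    ]
    pd.DataFrame(rows, columns=["genome_id", "completeness", "contamination"]).to_csv(
        path, sep="\t", index=False
    )
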