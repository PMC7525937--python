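"""Derivation of a Core set of Minimal Functions (CMF) from minimal genomes.

Two engineered minimal bacterial genomes do not overlap perfectly, so the
reference gene set is taken as the *intersection* of their confidently
annotated functions: gene calls whose product is flagged "hypothetical" or
"putative" are dropped (the certainty filter), the survivors are mapped to
normalized function keys, and keys present in every reference genome form
the CMF.  Matching is by string identity on the normalized key — gene symbol
first, product string as fallback — not by sequence similarity.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .annotation_io import FeatureType, GeneRecord, GenomeAnnotation

__all__ = [
    "CMFEntry",
    "CMFSet",
    "DEFAULT_UNCERTAINTY_MARKERS",
    "normalize_key",
    "filter_certain_genes",
    "build_cmf",
    "genome_cmf_coverage",
    "read_category_map",
    "assign_functional_categories",
    "write_cmf_table",
    "read_cmf_table",
]

DEFAULT_UNCERTAINTY_MARKERS: tuple[str, ...] = ("hypothetical", "putative")

UNASSIGNED_CATEGORY = "unassigned"


@dataclass(frozen=True)
class CMFEntry:
    """One core minimal function: a normalized key with its provenance."""

    key: str
    gene_symbol: str | None
    product: str
    feature_type: FeatureType
    categories: tuple[str, ...] = ()
    source_genomes: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if not self.key:
            raise ValueError("CMFEntry.key must be non-empty")


@dataclass
class CMFSet:
    """An ordered, duplicate-free reference list of core minimal functions.

    Entries are kept sorted lexicographically by key so that any two builds
    from the same inputs are identical, column orders downstream included.
    """

    entries: list[CMFEntry]
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.entries = sorted(self.entries, key=lambda e: e.key)
        keys = [e.key for e in self.entries]
        if len(keys) != len(set(keys)):
            raise ValueError("CMFSet entries contain duplicate keys")

    @property
    def keys(self) -> list[str]:
        return [e.key for e in self.entries]

    def key_set(self) -> frozenset[str]:
        return frozenset(e.key for e in self.entries)

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self):
        return iter(self.entries)


# ---------------------------------------------------------------------------
# key normalization
# ---------------------------------------------------------------------------

_COPY_SUFFIX = re.compile(r"_\d+$")
_NON_KEY_CHARS = re.compile(r"[^\w\s-]")
_WHITESPACE = re.compile(r"\s+")
_TRNA_ISOTYPE = re.compile(r"trna-([a-z]+)")


def _normalize_product(product: str) -> str:
    p = _NON_KEY_CHARS.sub("", product.lower())
    return _WHITESPACE.sub(" ", p).strip()


def normalize_key(record: GeneRecord) -> str:
    """Map a gene record to its canonical function key.

    CDS: lowercase gene symbol with any trailing ``_<n>`` multi-copy suffix
    removed; records without a symbol fall back to the lowercased product
    with whitespace collapsed and punctuation (except hyphens) stripped.
    tRNAs are keyed by isotype only (``trna-ala``), discarding the
    anticodon, so isoacceptor variants count as one function.  rRNAs are
    keyed by subunit (``rrna-16s``/``rrna-23s``/``rrna-5s``), tmRNA by the
    constant ``tmrna``.
    """
    ft = record.feature_type
    if ft is FeatureType.TRNA:
        m = _TRNA_ISOTYPE.search(record.product.lower())
        if m:
            return f"trna-{m.group(1)}"
        warnings.warn(
            f"unparseable tRNA isotype in product {record.product!r}; "
            "falling back to normalized product",
            stacklevel=2,
        )
        return _normalize_product(record.product)
    if ft is FeatureType.RRNA:
        compact = record.product.lower().replace(" ", "")
        for token in ("16s", "23s", "5s"):
            if token in compact:
                return f"rrna-{token}"
        warnings.warn(
            f"unrecognized rRNA subunit in product {record.product!r}; "
            "falling back to normalized product",
            stacklevel=2,
        )
        return _normalize_product(record.product)
    if ft is FeatureType.TMRNA:
        return "tmrna"
    if record.gene_symbol:
        return _COPY_SUFFIX.sub("", record.gene_symbol.lower())
    return _normalize_product(record.product)


# ---------------------------------------------------------------------------
# certainty filter and CMF construction
# ---------------------------------------------------------------------------

def filter_certain_genes(
    annotation: GenomeAnnotation,
    uncertainty_markers: Sequence[str] = DEFAULT_UNCERTAINTY_MARKERS,
    exclusion_list: Iterable[str] = (),
) -> GenomeAnnotation:
    """Keep only gene calls assigned with certainty.

    A record is dropped if its product contains any uncertainty marker
    (case-insensitive substring match) or if its normalized key is on the
    explicit exclusion list; order is preserved.  Idempotent.
    """
    if not uncertainty_markers:
        raise ValueError("uncertainty_markers must be non-empty")
    markers = [m.lower() for m in uncertainty_markers]
    excluded = {k.lower() for k in exclusion_list}
    kept = [
        g
        for g in annotation.genes
        if not any(m in g.product.lower() for m in markers)
        and normalize_key(g) not in excluded
    ]
    return GenomeAnnotation(
        genome_id=annotation.genome_id,
        source_group=annotation.source_group,
        genes=kept,
        quality=annotation.quality,
    )


def _certain_key_map(
    annotation: GenomeAnnotation,
    uncertainty_markers: Sequence[str],
    exclusion_list: Iterable[str],
) -> dict[str, GeneRecord]:
    """Normalized key -> first representative record (multi-copy collapse)."""
    filtered = filter_certain_genes(annotation, uncertainty_markers, exclusion_list)
    keymap: dict[str, GeneRecord] = {}
    for rec in filtered.genes:
        keymap.setdefault(normalize_key(rec), rec)
    return keymap


def build_cmf(
    annotations: Sequence[GenomeAnnotation],
    require_all: bool = True,
    uncertainty_markers: Sequence[str] = DEFAULT_UNCERTAINTY_MARKERS,
    exclusion_list: Iterable[str] = (),
) -> CMFSet:
    """Build the CMF from reference minimal-genome annotations.

    Each annotation is certainty-filtered and mapped to normalized keys;
    with ``require_all`` (the default) only keys present in *every*
    reference genome are retained, otherwise the union is taken.  Each
    entry carries the product string of the first source genome listing it.
    """
    if not annotations:
        raise ValueError("build_cmf requires at least one annotation")
    if require_all and len(annotations) < 2:
        raise ValueError("require_all intersection needs >= 2 reference genomes")
    exclusion_list = list(exclusion_list)
    keymaps = [
        _certain_key_map(a, uncertainty_markers, exclusion_list) for a in annotations
    ]
    if require_all:
        retained = set(keymaps[0])
        for km in keymaps[1:]:
            retained &= set(km)
    else:
        retained = set().union(*keymaps)
    entries = []
    for key in retained:
        rep = next(km[key] for km in keymaps if key in km)
        sources = frozenset(
            a.genome_id for a, km in zip(annotations, keymaps) if key in km
        )
        entries.append(
            CMFEntry(
                key=key,
                gene_symbol=rep.gene_symbol,
                product=rep.product,
                feature_type=rep.feature_type,
                source_genomes=sources,
            )
        )
    if not entries:
        warnings.warn("CMF intersection is empty", stacklevel=2)
    return CMFSet(
        entries=entries,
        provenance={
            "reference_genomes": [a.genome_id for a in annotations],
            "require_all": require_all,
            "uncertainty_markers": list(uncertainty_markers),
            "exclusion_list": exclusion_list,
        },
    )


def genome_cmf_coverage(cmf: CMFSet, annotation: GenomeAnnotation) -> float:
    """Percent of a genome's distinct function keys that lie in the CMF.

    The denominator is the number of distinct normalized keys over *all*
    annotated features of the genome (certain or not); multi-copy genes
    count once.  Reported to one decimal.
    """
    if not annotation.genes:
        raise ValueError(f"genome {annotation.genome_id!r} has no annotated features")
    keys = {normalize_key(g) for g in annotation.genes}
    return round(100.0 * len(keys & cmf.key_set()) / len(keys), 1)


# ---------------------------------------------------------------------------
# functional categories
# ---------------------------------------------------------------------------

def read_category_map(path: str | Path) -> dict[str, list[str]]:
    """Read a two-column TSV mapping key/gene symbol -> functional category.

    A key may appear on several rows (multi-pathway genes); categories
    accumulate in file order.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if df.shape[1] < 2:
        raise ValueError(f"{path}: category map needs two columns (key, category)")
    mapping: dict[str, list[str]] = {}
    for key, cat in zip(df.iloc[:, 0], df.iloc[:, 1]):
        key = str(key).lower()
        cat = str(cat)
        mapping.setdefault(key, [])
        if cat not in mapping[key]:
            mapping[key].append(cat)
    return mapping


def assign_functional_categories(
    cmf: CMFSet, mapping: Mapping[str, Sequence[str]]
) -> CMFSet:
    """Attach functional-class labels to each CMF entry.

    Entries are matched by normalized key, then by gene symbol; unmapped
    entries get the single category ``"unassigned"``.  Mapping keys that
    match no entry are reported with a warning (likely typos in the map).
    """
    matchable = {e.key for e in cmf} | {
        e.gene_symbol.lower() for e in cmf if e.gene_symbol
    }
    unknown = sorted(set(mapping) - matchable)
    if unknown:
        warnings.warn(
            f"category map keys matching no CMF entry ignored: {unknown}",
            stacklevel=2,
        )
    entries = []
    for e in cmf:
        cats = list(mapping.get(e.key, []))
        if not cats and e.gene_symbol:
            cats = list(mapping.get(e.gene_symbol.lower(), []))
        entries.append(replace(e, categories=tuple(cats) or (UNASSIGNED_CATEGORY,)))
    return CMFSet(entries=entries, provenance=dict(cmf.provenance))


def category_counts(cmf: CMFSet) -> pd.Series:
    """Number of CMF entries per functional category (multi-class counted in each)."""
    counts: dict[str, int] = {}
    for e in cmf:
        for c in e.categories or (UNASSIGNED_CATEGORY,):
            counts[c] = counts.get(c, 0) + 1
    return pd.Series(counts, dtype=int).sort_index()


# ---------------------------------------------------------------------------
# CMF table round trip
# ---------------------------------------------------------------------------

def write_cmf_table(cmf: CMFSet, path: str | Path) -> None:
    """Write the CMF as TSV: key, gene_symbol, product, feature_type, category, source_genomes."""
    rows = [
        {
            "key": e.key,
            "gene_symbol": e.gene_symbol or "",
            "product": e.product,
            "feature_type": e.feature_type.value,
            "category": "|".join(e.categories),
            "source_genomes": ",".join(sorted(e.source_genomes)),
        }
        for e in cmf
    ]
    pd.DataFrame(
        rows,
        columns=["key", "gene_symbol", "product", "feature_type", "category", "source_genomes"],
    ).to_csv(path, sep="\t", index=False)


def read_cmf_table(path: str | Path) -> CMFSet:
    """Read a CMF table written by :func:`write_cmf_table` (bit-exact round trip)."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    entries = [
        CMFEntry(
            key=row.key,
            gene_symbol=row.gene_symbol or None,
            product=row.product,
            feature_type=FeatureType(row.feature_type),
            categories=tuple(c for c in row.category.split("|") if c),
            source_genomes=frozenset(s for s in row.source_genomes.split(",") if s),
        )
        for row in df.itertuples(index=False)
    ]
    return CMFSet(entries=entries, provenance={"loaded_from": str(path)})
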