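"""Synthetic cohorts of annotated genomes with known ground truth.

Real screening campaigns compare thousands of downloaded genomes against a
reference set of core minimal functions; this module generates stand-in
cohorts whose statistical structure matches the study conditions the
pipeline is meant to detect, so every stage is testable without downloads:

* a fixed catalog of 183 core minimal functions (44 ribosomal proteins,
  20 aminoacyl-tRNA ligases, 20 tRNA isotypes, the three rRNAs, tmRNA,
  replication/transcription/translation machinery and a core-metabolism
  block), each entry of which round-trips through the key normalizer;
* a *synthetic* pair of minimal-genome annotations whose certain-gene
  intersection is exactly that catalog, for exercising CMF derivation;
* a two-group benchmark cohort: isolate-like genomes (high, low-variance
  adherence) versus MAG-like genomes (lower, high-variance adherence, a
  16S-like gene depleted in ~80%, four hard genes missing in >85%), with
  a simulated completeness score positively correlated with adherence.

The generative model is deliberately simple: each genome draws a true
completeness ``c`` from its group's Beta distribution and contains CMF
gene ``j`` with probability ``c * q_j``, where ``q_j`` is a per-gene
detectability; contamination adds Poisson-many decoy genes whose keys are
disjoint from the catalog.  Simulated completeness is ``100 c`` plus
Gaussian reporting noise, clamped to [0, 100].
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence
from urllib.parse import quote

import numpy as np
import pandas as pd

from .annotation_io import (
    FeatureType,
    GeneRecord,
    GenomeAnnotation,
    QualityScore,
    SourceGroup,
    write_quality_table,
)
from .cmf_builder import CMFEntry, CMFSet, normalize_key

__all__ = [
    "GroupSpec",
    "CohortSpec",
    "CohortTruth",
    "reference_function_catalog",
    "synthetic_cmf",
    "synthetic_minimal_genome_pair",
    "default_category_map",
    "make_decoy_pool",
    "sample_genome",
    "generate_cohort",
    "benchmark_cohort_spec",
    "write_cohort",
    "write_genome_gff3",
]

GIP = "genetic information processing"
MET = "metabolism"
EIP = "environmental information processing"
CP = "cellular processes"

_AA = {
    "ala": "Alanine", "arg": "Arginine", "asn": "Asparagine", "asp": "Aspartate",
    "cys": "Cysteine", "gln": "Glutamine", "glu": "Glutamate", "gly": "Glycine",
    "his": "Histidine", "ile": "Isoleucine", "leu": "Leucine", "lys": "Lysine",
    "met": "Methionine", "phe": "Phenylalanine", "pro": "Proline", "ser": "Serine",
    "thr": "Threonine", "trp": "Tryptophan", "tyr": "Tyrosine", "val": "Valine",
}
_ANTICODON = {
    "ala": "tgc", "arg": "acg", "asn": "gtt", "asp": "gtc", "cys": "gca",
    "gln": "ttg", "glu": "ttc", "gly": "gcc", "his": "gtg", "ile": "gat",
    "leu": "tag", "lys": "ttt", "met": "cat", "phe": "gaa", "pro": "tgg",
    "ser": "tga", "thr": "tgt", "trp": "cca", "tyr": "gta", "val": "tac",
}

_LIGASE_SYMBOL = {
    "ala": "alaS", "arg": "argS", "asn": "asnS", "asp": "aspS", "cys": "cysS",
    "gln": "glnS", "glu": "gltX", "gly": "glyS", "his": "hisS", "ile": "ileS",
    "leu": "leuS", "lys": "lysS", "met": "metG", "phe": "pheS", "pro": "proS",
    "ser": "serS", "thr": "thrS", "trp": "trpS", "tyr": "tyrS", "val": "valS",
}

_NAMED_CDS: list[tuple[str, str, tuple[str, ...]]] = [
    # replication and repair
    ("dnaA", "Chromosomal replication initiator protein DnaA", (GIP,)),
    ("dnaB", "Replicative DNA helicase", (GIP,)),
    ("dnaE", "DNA polymerase III subunit alpha", (GIP,)),
    ("dnaG", "DNA primase", (GIP,)),
    ("dnaN", "DNA polymerase III subunit beta", (GIP,)),
    ("dnaX", "DNA polymerase III subunit tau", (GIP,)),
    ("gyrA", "DNA gyrase subunit A", (GIP,)),
    ("gyrB", "DNA gyrase subunit B", (GIP,)),
    ("parC", "DNA topoisomerase 4 subunit A", (GIP,)),
    ("parE", "DNA topoisomerase 4 subunit B", (GIP,)),
    ("polA", "DNA polymerase I", (GIP,)),
    ("ligA", "DNA ligase", (GIP,)),
    ("ssb", "Single-stranded DNA-binding protein", (GIP,)),
    ("recA", "Protein RecA", (GIP,)),
    ("holA", "DNA polymerase III subunit delta", (GIP,)),
    ("holB", "DNA polymerase III subunit delta'", (GIP,)),
    # transcription
    ("rpoA", "DNA-directed RNA polymerase subunit alpha", (GIP,)),
    ("rpoB", "DNA-directed RNA polymerase subunit beta", (GIP,)),
    ("rpoC", "DNA-directed RNA polymerase subunit beta'", (GIP,)),
    ("rpoD", "RNA polymerase sigma factor RpoD", (GIP,)),
    ("rpoZ", "DNA-directed RNA polymerase subunit omega", (GIP,)),
    ("nusA", "Transcription termination/antitermination protein NusA", (GIP,)),
    ("nusB", "Transcription antitermination protein NusB", (GIP,)),
    ("nusG", "Transcription termination/antitermination protein NusG", (GIP,)),
    ("greA", "Transcription elongation factor GreA", (GIP,)),
    # translation factors
    ("infA", "Translation initiation factor IF-1", (GIP,)),
    ("infB", "Translation initiation factor IF-2", (GIP,)),
    ("infC", "Translation initiation factor IF-3", (GIP,)),
    ("fusA", "Elongation factor G", (GIP,)),
    ("tsf", "Elongation factor Ts", (GIP,)),
    ("tuf", "Elongation factor Tu", (GIP,)),
    ("prfA", "Peptide chain release factor 1", (GIP,)),
    ("prfB", "Peptide chain release factor 2", (GIP,)),
    ("frr", "Ribosome-recycling factor", (GIP,)),
    ("efp", "Elongation factor P", (GIP,)),
    ("rbfA", "Ribosome-binding factor A", (GIP,)),
    # protein folding, processing and secretion
    ("secA", "Protein translocase subunit SecA", (GIP, EIP, CP)),
    ("secY", "Protein translocase subunit SecY", (GIP, EIP, CP)),
    ("secE", "Protein translocase subunit SecE", (GIP,)),
    ("yidC", "Membrane protein insertase YidC", (GIP,)),
    ("ffh", "Signal recognition particle protein", (GIP,)),
    ("ftsY", "Signal recognition particle receptor FtsY", (GIP,)),
    ("dnaK", "Chaperone protein DnaK", (GIP,)),
    ("dnaJ", "Chaperone protein DnaJ", (GIP,)),
    ("grpE", "Protein GrpE", (GIP,)),
    ("groL", "60 kDa chaperonin", (GIP,)),
    ("groS", "10 kDa chaperonin", (GIP,)),
    ("tig", "Trigger factor", (GIP,)),
    ("map", "Methionine aminopeptidase", (GIP,)),
    ("def", "Peptide deformylase", (GIP,)),
    ("fmt", "Methionyl-tRNA formyltransferase", (GIP,)),
    ("pth", "Peptidyl-tRNA hydrolase", (GIP,)),
    ("ftsH", "ATP-dependent zinc metalloprotease FtsH", (CP,)),
    # RNA processing and modification
    ("trmD", "tRNA (guanine-N(1)-)-methyltransferase", (GIP,)),
    ("truB", "tRNA pseudouridine synthase B", (GIP,)),
    ("mnmA", "tRNA-specific 2-thiouridylase MnmA", (GIP,)),
    ("mnmE", "tRNA modification GTPase MnmE", (GIP,)),
    ("mnmG", "tRNA uridine 5-carboxymethylaminomethyl modification enzyme MnmG", (GIP,)),
    ("ksgA", "Ribosomal RNA small subunit methyltransferase A", (GIP,)),
    ("rnpA", "Ribonuclease P protein component", (GIP,)),
    ("rnc", "Ribonuclease 3", (GIP,)),
    # central metabolism
    ("pgi", "Glucose-6-phosphate isomerase", (MET,)),
    ("pfkA", "ATP-dependent 6-phosphofructokinase", (MET,)),
    ("fba", "Fructose-bisphosphate aldolase", (MET,)),
    ("tpiA", "Triosephosphate isomerase", (MET,)),
    ("gapA", "Glyceraldehyde-3-phosphate dehydrogenase", (MET,)),
    ("pgk", "Phosphoglycerate kinase", (MET, EIP)),
    ("gpmA", "2,3-bisphosphoglycerate-dependent phosphoglycerate mutase", (MET,)),
    ("eno", "Enolase", (MET, GIP, EIP)),
    ("pyk", "Pyruvate kinase", (MET,)),
    ("aceE", "Pyruvate dehydrogenase E1 component", (MET,)),
    ("aceF", "Dihydrolipoyllysine-residue acetyltransferase component of pyruvate dehydrogenase complex", (MET,)),
    ("lpdA", "Dihydrolipoyl dehydrogenase", (MET,)),
    ("atpA", "ATP synthase subunit alpha", (MET,)),
    ("atpB", "ATP synthase subunit a", (MET,)),
    ("atpC", "ATP synthase epsilon chain", (MET,)),
    ("atpD", "ATP synthase subunit beta", (MET,)),
    ("atpE", "ATP synthase subunit c", (MET,)),
    ("atpF", "ATP synthase subunit b", (MET,)),
    ("atpG", "ATP synthase gamma chain", (MET,)),
    ("atpH", "ATP synthase subunit delta", (MET,)),
    ("adk", "Adenylate kinase", (MET,)),
    ("cmk", "Cytidylate kinase", (MET,)),
    ("gmk", "Guanylate kinase", (MET,)),
    ("tmk", "Thymidylate kinase", (MET,)),
    ("ndk", "Nucleoside diphosphate kinase", (MET,)),
    ("pyrG", "CTP synthase", (MET,)),
    ("pyrH", "Uridylate kinase", (MET,)),
    ("prs", "Ribose-phosphate pyrophosphokinase", (MET,)),
    ("glk", "Glucokinase", (MET,)),
    ("pgm", "Phosphoglucomutase", (MET,)),
    ("hisB", "Histidine biosynthesis bifunctional protein HisB", (MET,)),
    # cell division
    ("ftsZ", "Cell division protein FtsZ", (CP,)),
    ("ftsA", "Cell division protein FtsA", (CP,)),
    ("sepF", "Cell division protein SepF", (CP,)),
]


def reference_function_catalog() -> list[CMFEntry]:
    """The fixed 183-entry catalog of core minimal functions.

    Entry keys are exactly what :func:`~cmfscan.cmf_builder.normalize_key`
    produces for the corresponding gene records, so generated annotations
    round-trip through screening without loss.
    """
    entries: list[CMFEntry] = []

    def add(symbol, product, ftype, cats):
        rec = GeneRecord(ftype, symbol, product, "catalog")
        entries.append(
            CMFEntry(
                key=normalize_key(rec),
                gene_symbol=symbol,
                product=product,
                feature_type=ftype,
                categories=tuple(cats),
            )
        )

    for i in range(1, 22):  # 30S ribosomal proteins S1-S21
        add(f"rps{chr(ord('A') + i - 1)}", f"30S ribosomal protein S{i}", FeatureType.CDS, (GIP,))
    for i in range(1, 7):  # 50S L1-L6
        add(f"rpl{chr(ord('A') + i - 1)}", f"50S ribosomal protein L{i}", FeatureType.CDS, (GIP,))
    for j, i in enumerate(range(9, 25)):  # 50S L9-L24 -> rplI..rplX
        add(f"rpl{chr(ord('I') + j)}", f"50S ribosomal protein L{i}", FeatureType.CDS, (GIP,))
    add("rpmA", "50S ribosomal protein L27", FeatureType.CDS, (GIP,))
    for iso in sorted(_AA):
        add(
            _LIGASE_SYMBOL[iso],
            f"{_AA[iso]}--tRNA ligase",
            FeatureType.CDS,
            (GIP,),
        )
    for symbol, product, cats in _NAMED_CDS:
        add(symbol, product, FeatureType.CDS, cats)
    for iso in sorted(_AA):
        add(None, f"tRNA-{iso.capitalize()}({_ANTICODON[iso]})", FeatureType.TRNA, (GIP,))
    for sub in ("16S", "23S", "5S"):
        add(None, f"{sub} ribosomal RNA", FeatureType.RRNA, (GIP,))
    add(None, "transfer-messenger RNA, SsrA", FeatureType.TMRNA, (GIP,))
    assert len(entries) == 183, f"catalog size {len(entries)} != 183"
    assert len({e.key for e in entries}) == 183, "catalog keys not unique"
    return entries


def synthetic_cmf() -> CMFSet:
    """The catalog as a ready-made CMFSet (no derivation step)."""
    return CMFSet(
        entries=reference_function_catalog(),
        provenance={"reference_genomes": ["SYNMIN-A", "SYNMIN-B"], "synthetic": True},
    )


def default_category_map() -> dict[str, list[str]]:
    """Key -> functional classes for the catalog entries."""
    return {e.key: list(e.categories) for e in reference_function_catalog()}


def _record(entry: CMFEntry, locus: str) -> GeneRecord:
    return GeneRecord(entry.feature_type, entry.gene_symbol, entry.product, locus)


def synthetic_minimal_genome_pair() -> tuple[GenomeAnnotation, GenomeAnnotation]:
    """A synthetic stand-in pair of minimal-genome annotations.

    Both genomes carry every catalog function with confident product
    strings; each additionally carries genome-specific certain genes and a
    block of hypothetical calls, sized so that the catalog covers 91.0%
    and 83.9% of the two genomes' distinct keys under the
    all-features-denominator convention.  Feeding the pair to
    :func:`~cmfscan.cmf_builder.build_cmf` recovers exactly the
    183-function catalog.
    """
    catalog = reference_function_catalog()

    def build(gid: str, n_unique: int, n_hypo: int, unique_stem: str) -> GenomeAnnotation:
        genes: list[GeneRecord] = []
        for i, e in enumerate(catalog, start=1):
            genes.append(_record(e, f"{gid}_{i:05d}"))
        base = len(genes)
        for i in range(1, n_unique + 1):
            genes.append(
                GeneRecord(
                    FeatureType.CDS,
                    None,
                    f"{unique_stem} domain-containing protein {i}",
                    f"{gid}_{base + i:05d}",
                )
            )
        base = len(genes)
        for i in range(1, n_hypo + 1):
            genes.append(
                GeneRecord(
                    FeatureType.CDS, None, "hypothetical protein", f"{gid}_{base + i:05d}"
                )
            )
        # one multi-copy gene with the annotator's _2 suffix: collapses to tuf
        genes.append(
            GeneRecord(FeatureType.CDS, "tuf_2", "Elongation factor Tu", f"{gid}_tuf2")
        )
        return GenomeAnnotation(gid, SourceGroup.SYNTHETIC, genes)

    # distinct keys: 183 catalog + n_unique + 1 (all hypotheticals share a key)
    # -> 183/201 = 91.0% and 183/218 = 83.9%
    return (
        build("SYNMIN-A", 17, 9, "Membrane-anchored minimal-genome"),
        build("SYNMIN-B", 34, 11, "Cell-envelope biogenesis"),
    )


# ---------------------------------------------------------------------------
# cohort specification
# ---------------------------------------------------------------------------

@dataclass
class GroupSpec:
    """Generative parameters of one genome group."""

    name: str
    n_genomes: int
    source_group: SourceGroup
    completeness_alpha: float
    completeness_beta: float
    default_detectability: float
    detectability_overrides: dict[str, float] = field(default_factory=dict)
    contamination_rate: float = 5.0
    quality_noise_sd: float = 2.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.default_detectability <= 1.0:
            raise ValueError("default_detectability must be in [0, 1]")
        for k, q in self.detectability_overrides.items():
            if not 0.0 <= q <= 1.0:
                raise ValueError(f"detectability for {k!r} must be in [0, 1]")
        if self.n_genomes < 0 or self.contamination_rate < 0:
            raise ValueError("n_genomes and contamination_rate must be >= 0")

    def detectability(self, cmf_keys: Sequence[str]) -> np.ndarray:
        return np.array(
            [self.detectability_overrides.get(k, self.default_detectability) for k in cmf_keys]
        )

    def mean_completeness(self) -> float:
        return self.completeness_alpha / (self.completeness_alpha + self.completeness_beta)


@dataclass
class CohortSpec:
    """Full specification of a synthetic cohort."""

    groups: list[GroupSpec]
    cmf_size: int = 183
    decoy_pool_size: int = 300
    seed: int = 17


@dataclass
class CohortTruth:
    """Ground truth accompanying a generated cohort."""

    genome_ids: list[str]
    group_names: list[str]
    cmf_keys: list[str]
    presence: np.ndarray  # n_genomes x n_keys, int8
    completeness_true: np.ndarray  # in [0, 1]
    detectability: dict[str, np.ndarray]  # group name -> per-key q
    quality: dict[str, QualityScore]  # simulated CheckM-style scores


_DECOY_FAMILIES = [
    "ABC transporter ATP-binding protein",
    "MFS family transporter",
    "Two-component sensor histidine kinase",
    "LysR family transcriptional regulator",
    "Glycosyltransferase family 2 protein",
    "Site-specific DNA recombinase",
    "Type II restriction endonuclease",
    "Cell surface adhesin repeat protein",
    "Phage tail fiber protein",
]


def make_decoy_pool(size: int, hypothetical_fraction: float = 0.1) -> list[GeneRecord]:
    """A pool of contamination decoy genes with keys disjoint from the catalog.

    A fixed fraction of the pool is flagged ``hypothetical protein`` so the
    certainty filter is exercised on contaminated inputs.
    """
    n_hypo = int(round(size * hypothetical_fraction))
    pool: list[GeneRecord] = []
    for i in range(size - n_hypo):
        fam = _DECOY_FAMILIES[i % len(_DECOY_FAMILIES)]
        pool.append(
            GeneRecord(FeatureType.CDS, None, f"{fam} D{i + 1:04d}", f"decoy_{i + 1:04d}")
        )
    for i in range(n_hypo):
        pool.append(
            GeneRecord(
                FeatureType.CDS, None, "hypothetical protein", f"decoy_h{i + 1:04d}"
            )
        )
    catalog_keys = {e.key for e in reference_function_catalog()}
    clash = {normalize_key(r) for r in pool} & catalog_keys
    assert not clash, f"decoy keys clash with catalog: {sorted(clash)[:5]}"
    return pool


def benchmark_cohort_spec(
    n_isolate: int = 400, n_mag: int = 1000, seed: int = 17
) -> CohortSpec:
    """The default two-group benchmark cohort.

    Emulates the contrast between curated isolate genomes and
    metagenome-assembled genomes: mean adherence ~93% with small spread in
    the isolate-like group versus ~68% with large spread in the MAG-like
    group; a 16S-like key undetectable in ~80% of MAG-like genomes; four
    hard genes (FtsH-, topoisomerase-4-, dihydrolipoyllysine
    acetyltransferase- and HisB-like) missing in >85%; 40 further genes
    missing in ~60%, so that 45 keys exceed the 50%-missing threshold; and
    simulated completeness rank-correlated with adherence at tau ~ 0.6.

    Detectability defaults are solved from the target group mean
    ``E[adherence] = E[c] * mean(q)``; Beta and noise parameters were
    fixed once by moment matching (see the methods note).
    """
    catalog = reference_function_catalog()
    cmf_keys = [e.key for e in catalog]

    isolate = GroupSpec(
        name="isolate_like",
        n_genomes=n_isolate,
        source_group=SourceGroup.NCBI,
        completeness_alpha=85.0,
        completeness_beta=4.4,
        default_detectability=1.0,  # replaced below
        contamination_rate=3.0,
        quality_noise_sd=2.0,
    )
    isolate.default_detectability = round(
        min(1.0, 0.932 / isolate.mean_completeness()), 5
    )

    hard = {"ftsh": 0.15, "parc": 0.15, "acef": 0.15, "hisb": 0.15}
    overrides = {"rrna-16s": 0.25, **hard}
    soft_candidates = [
        e.key
        for e in catalog
        if e.feature_type is FeatureType.CDS and e.key not in hard
    ]
    for k in sorted(soft_candidates)[:40]:
        overrides[k] = 0.5

    mag = GroupSpec(
        name="mag_like",
        n_genomes=n_mag,
        source_group=SourceGroup.UMGS,
        completeness_alpha=10.72,
        completeness_beta=2.68,
        default_detectability=1.0,  # replaced below
        detectability_overrides=overrides,
        contamination_rate=12.0,
        quality_noise_sd=6.3,
    )
    target_mean_q = 0.679 / mag.mean_completeness()
    n_keys = len(cmf_keys)
    q_sum_overrides = sum(overrides.values())
    mag.default_detectability = round(
        (n_keys * target_mean_q - q_sum_overrides) / (n_keys - len(overrides)), 5
    )
    return CohortSpec(groups=[isolate, mag], cmf_size=len(cmf_keys), seed=seed)


# ---------------------------------------------------------------------------
# sampling
# ---------------------------------------------------------------------------

def sample_genome(
    group: GroupSpec,
    cmf: CMFSet,
    decoys: Sequence[GeneRecord],
    rng: np.random.Generator,
    genome_id: str,
) -> tuple[GenomeAnnotation, dict]:
    """Draw one genome: completeness, per-gene presence, decoy contamination."""
    if len(cmf) == 0:
        raise ValueError("cannot sample against an empty CMF")
    c = float(rng.beta(group.completeness_alpha, group.completeness_beta))
    q = group.detectability(cmf.keys)
    present = rng.random(len(cmf)) < c * q
    n_decoys = int(rng.poisson(group.contamination_rate))
    n_decoys = min(n_decoys, len(decoys))
    decoy_idx = (
        rng.choice(len(decoys), size=n_decoys, replace=False)
        if n_decoys
        else np.empty(0, dtype=int)
    )
    genes: list[GeneRecord] = []
    counter = 0
    for e, keep in zip(cmf.entries, present):
        if keep:
            counter += 1
            genes.append(_record(e, f"{genome_id}_{counter:05d}"))
    for i in decoy_idx:
        counter += 1
        d = decoys[int(i)]
        genes.append(GeneRecord(d.feature_type, d.gene_symbol, d.product, f"{genome_id}_{counter:05d}"))
    completeness_sim = float(np.clip(100.0 * c + rng.normal(0.0, group.quality_noise_sd), 0.0, 100.0))
    contamination_sim = round(100.0 * n_decoys / max(1, counter), 2)
    annotation = GenomeAnnotation(genome_id, group.source_group, genes)
    truth_row = {
        "genome_id": genome_id,
        "group": group.name,
        "completeness_true": c,
        "presence": present.astype("int8"),
        "quality": QualityScore(completeness_sim, contamination_sim),
    }
    return annotation, truth_row


def generate_cohort(
    spec: CohortSpec, out_dir: str | Path | None = None
) -> tuple[list[GenomeAnnotation], CohortTruth]:
    """Generate a full cohort, deterministically under the spec's seed.

    Per-genome random streams are spawned from one root seed sequence, so
    the cohort is reproducible and individual genomes do not depend on
    generation order.  With ``out_dir`` set, writes one GFF3 per genome
    plus ``groups.tsv``, ``checkm.tsv`` and the truth presence matrix.
    """
    catalog = reference_function_catalog()
    if spec.cmf_size > len(catalog):
        raise ValueError(
            f"cmf_size {spec.cmf_size} exceeds catalog size {len(catalog)}"
        )
    cmf = CMFSet(entries=catalog[: spec.cmf_size] if spec.cmf_size < len(catalog) else catalog,
                 provenance={"synthetic": True})
    decoys = make_decoy_pool(spec.decoy_pool_size)
    root = np.random.SeedSequence(spec.seed)
    total = sum(g.n_genomes for g in spec.groups)
    if total == 0:
        warnings.warn("cohort spec has zero genomes in every group", stacklevel=2)
    child_seeds = root.spawn(total)
    annotations: list[GenomeAnnotation] = []
    ids: list[str] = []
    names: list[str] = []
    pres_rows: list[np.ndarray] = []
    c_true: list[float] = []
    quality: dict[str, QualityScore] = {}
    i = 0
    for group in spec.groups:
        for j in range(group.n_genomes):
            gid = f"{group.name}_{j + 1:05d}"
            rng = np.random.default_rng(child_seeds[i])
            ann, row = sample_genome(group, cmf, decoys, rng, gid)
            annotations.append(ann)
            ids.append(gid)
            names.append(group.name)
            pres_rows.append(row["presence"])
            c_true.append(row["completeness_true"])
            quality[gid] = row["quality"]
            i += 1
    truth = CohortTruth(
        genome_ids=ids,
        group_names=names,
        cmf_keys=list(cmf.keys),
        presence=(
            np.stack(pres_rows) if pres_rows else np.zeros((0, len(cmf)), dtype="int8")
        ),
        completeness_true=np.array(c_true),
        detectability={g.name: g.detectability(cmf.keys) for g in spec.groups},
        quality=quality,
    )
    if out_dir is not None:
        write_cohort(annotations, truth, out_dir)
    return annotations, truth


# ---------------------------------------------------------------------------
# on-disk representation
# ---------------------------------------------------------------------------

def _gff3_escape(value: str) -> str:
    return quote(value, safe=" ()[]'.:^*$@!+?|/-_")


def write_genome_gff3(annotation: GenomeAnnotation, path: str | Path) -> None:
    """Write an annotation as minimal single-contig GFF3 with synthetic coordinates."""
    lines = ["##gff-version 3"]
    start = 1
    seqid = f"{annotation.genome_id}_contig1"
    lines.append(f"##sequence-region {seqid} 1 {max(1, len(annotation.genes)) * 1000}")
    for rec in annotation.genes:
        end = start + 899
        attrs = [f"ID={rec.locus_id}", f"locus_tag={rec.locus_id}"]
        if rec.gene_symbol:
            attrs.append(f"gene={_gff3_escape(rec.gene_symbol)}")
        attrs.append(f"product={_gff3_escape(rec.product)}")
        lines.append(
            "\t".join(
                [
                    seqid,
                    "cmfscan_simulator",
                    rec.feature_type.value,
                    str(start),
                    str(end),
                    ".",
                    "+",
                    "0" if rec.feature_type is FeatureType.CDS else ".",
                    ";".join(attrs),
                ]
            )
        )
        start = end + 101
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def write_cohort(
    annotations: Sequence[GenomeAnnotation], truth: CohortTruth, out_dir: str | Path
) -> None:
    """Write GFF3s, group labels, simulated quality scores and the truth matrix."""
    out = Path(out_dir)
    genome_dir = out / "genomes"
    genome_dir.mkdir(parents=True, exist_ok=True)
    for ann in annotations:
        write_genome_gff3(ann, genome_dir / f"{ann.genome_id}.gff")
    pd.DataFrame(
        {
            "genome_id": [a.genome_id for a in annotations],
            "source_group": [a.source_group.value for a in annotations],
        }
    ).to_csv(out / "groups.tsv", sep="\t", index=False)
    write_quality_table(truth.quality, out / "checkm.tsv")
    tdf = pd.DataFrame(truth.presence, columns=truth.cmf_keys)
    tdf.insert(0, "group", truth.group_names)
    tdf.insert(0, "genome_id", truth.genome_ids)
    tdf.insert(2, "completeness_true", truth.completeness_true)
    tdf.to_csv(out / "truth.tsv", sep="\t", index=False)
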