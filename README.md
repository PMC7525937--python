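# cmfscan

Screen annotated prokaryotic genomes against a **Core set of Minimal
Functions (CMF)** — the genes confidently annotated in, and shared by, a
set of engineered minimal bacterial genomes — and quantify how completely
each genome represents that essential core.

## Who this is for

Metagenome-assembled genomes (MAGs) are binned from shotgun reads rather
than sequenced from isolates, and marker-gene completeness estimates
(CheckM-style scores) can paint an optimistic picture of how much of a
genome was actually recovered. A complementary quality lens is to ask:
does each genome carry the minimal functional core that any autonomously
living bacterium needs? `cmfscan` implements that screen end to end for
anyone comparing genome collections — MAG catalogues against isolate
references in particular.

## What it computes

1. **CMF derivation.** Annotations of two (or more) minimal genomes are
   certainty-filtered (gene calls whose product contains "hypothetical"
   or "putative" are dropped), mapped to normalized function keys (gene
   symbol first, with multi-copy `_n` suffixes removed; product string as
   fallback; tRNAs keyed by isotype, rRNAs by subunit), and intersected.
2. **Screening.** Every genome *i* gets a binary profile
   `x_ij ∈ {0,1}` over the CMF keys *j*, and an adherence statistic

   `adherence_i = 100 · (Σ_j x_ij) / |CMF|`,

   plus per-gene missingness profiles
   `missing_j = 100 · #{i in group : x_ij = 0} / n_group`.
3. **Group statistics.** Kruskal–Wallis and Wilcoxon/Mann–Whitney rank
   tests on adherence (exact by enumeration at small pooled *n*),
   Fisher's exact test (two-sided, point-probability ordering) on the
   Ward-cluster × source contingency, and Kendall's τ_b between
   adherence and completeness.
4. **Multivariate structure.** Jaccard and binary-Euclidean distances,
   Ward (D2) clustering, PCA of the centered binary matrix (whose score
   geometry reproduces the binary-Euclidean distances exactly), logistic
   PCA (a rank-constrained Bernoulli factorization fit by
   majorization–minimization), and a PERMANOVA pseudo-F permutation test

   `F = (SS_between/(g−1)) / (SS_within/(N−g))`,
   `p = (1 + #{F_perm ≥ F_obs}) / (1 + n_permutations)`.
5. **Synthetic cohorts.** A generator producing two-group benchmark
   cohorts with known ground truth (per-genome completeness `c_i`,
   per-gene detectability `q_j`, presence ~ Bernoulli(`c_i·q_j`)), so the
   whole pipeline is testable without downloading genomes.

## Worked example

```python
import cmfscan as cs
from cmfscan.cmf_builder import write_cmf_table
from cmfscan.pipeline import AnalysisConfig, run_full_analysis

# 1. derive a CMF from a (synthetic) minimal-genome pair
ref_a, ref_b = cs.synthetic_minimal_genome_pair()
cmf = cs.build_cmf([ref_a, ref_b])
print(len(cmf))                             # 183
print(cs.genome_cmf_coverage(cmf, ref_a))   # 91.0
print(cs.genome_cmf_coverage(cmf, ref_b))   # 83.9

# 2. simulate a small two-group cohort and run the full analysis
spec = cs.benchmark_cohort_spec(n_isolate=40, n_mag=100, seed=17)
cs.generate_cohort(spec, out_dir="demo/cohort")
write_cmf_table(cmf, "demo/cmf.tsv")
summary = run_full_analysis(AnalysisConfig(
    genome_dir="demo/cohort/genomes",
    groups_path="demo/cohort/groups.tsv",
    quality_path="demo/cohort/checkm.tsv",
    cmf_path="demo/cmf.tsv",
    output_dir="demo/out",
    n_permutations=999, seed=17,
))
```

The summary this prints (abridged) and what it means:

```
"groups": {
  "NCBI": {"n": 40,  "adherence_mean": 92.94,  "adherence_sd": 2.81},
  "UMGS": {"n": 100, "adherence_mean": 67.35,  "adherence_sd": 11.06}
}
"missing_count_above_threshold": {"UMGS": 43}
"permanova": {"pseudo_F": 19.57, "p_value": 0.001}
"adherence_completeness_kendall": 0.679
```

Isolate-like genomes carry ~93% of the essential core with little
spread; MAG-like genomes carry ~67% with a wide spread; 43 core genes
are missing from more than half the MAG-like group; the two groups
separate significantly in presence/absence space (PERMANOVA p = 0.001,
the minimum attainable at 999 permutations); and simulated completeness
rank-correlates with adherence (τ ≈ 0.68 at this small cohort size).
All per-stage artifacts (CMF table, presence matrix, adherence report,
distances, linkage, PCA scores) land in `demo/out/`.

The same workflow is available from the shell:

```bash
cmfscan build-cmf --genome refA.gff --genome refB.gff -o cmf.tsv
cmfscan simulate --n-isolate 400 --n-mag 1000 --seed 17 -o cohort/
cmfscan screen --cmf cmf.tsv --genomes cohort/genomes --groups cohort/groups.tsv \
               --checkm cohort/checkm.tsv -o matrix.tsv --report report.tsv
cmfscan run --config config.json
```

Real genome collections can be screened the same way: point
`genome_dir` at a directory of GFF3 files (or 7-column feature tables)
produced by a standard prokaryotic annotator, e.g. fetched with
`datasets download genome accession ...` / ENA bulk download and
annotated with Prokka, and supply the matching CheckM table.

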