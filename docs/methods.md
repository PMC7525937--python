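# Methods

## The screen

The reference object is a Core set of Minimal Functions (CMF): gene-level
functions confidently annotated in, and shared by, every genome of a
reference set of minimal bacterial genomes. The package derives it, scores
arbitrary annotated genomes against it, and tests whether groups of
genomes differ in how completely they represent it.

### Function identity

There is no sequence comparison anywhere: two gene calls represent the
same function iff their *normalized keys* are equal.

* CDS with a gene symbol: lowercase symbol, with a trailing `_<digits>`
  multi-copy suffix removed (annotators label extra copies `tuf_2`,
  `tuf_3`, ...). Symbols are the most stable identifier across runs of
  the same annotator.
* CDS without a symbol: lowercased product string, whitespace collapsed,
  punctuation other than hyphens stripped. This is the fallback because
  many draft-genome gene calls carry a product but no symbol.
* tRNA: `trna-<isotype>` — the anticodon is discarded, so isoacceptor
  variants of one amino acid count as a single function. A product from
  which no isotype can be parsed falls back to the normalized product
  string, with a warning.
* rRNA: `rrna-16s` / `rrna-23s` / `rrna-5s`; tmRNA: the constant `tmrna`.

### CMF construction

Each reference annotation passes a *certainty filter*: records whose
product contains `hypothetical` or `putative` (case-insensitive
substring) are dropped, as is anything on an explicit, version-controlled
exclusion list (empty by default; this replaces any irreproducible manual
curation step). Surviving records map to keys, duplicates within one
genome collapse, and keys present in **every** reference genome form the
CMF (`require_all=True`; the union is available for exploratory use).
Entries are sorted lexicographically by key, so the derivation is
deterministic and symmetric in the order of input genomes.

*Coverage* of a genome by a CMF is `100 · |CMF ∩ keys(genome)| /
|keys(genome)|`, where the denominator counts the distinct keys of **all**
annotated features, certain or not. The denominator convention is a
genuine design choice (certain-only and feature-count denominators are
equally defensible); all-features/distinct-keys is the default because it
answers "how much of what the annotator saw is core".

### Screening and adherence

Screened genomes are **not** certainty-filtered: a confidently binned MAG
gene counts as evidence of presence even if its product string would fail
the reference filter. (The reference filter exists to keep uncertain
calls *out of the reference set*; applying it to query genomes would
conflate annotation style with gene absence. The behaviour is
configurable via `apply_certainty_filter`.) Presence is duplication-
invariant; adherence is `100 · Σ_j x_ij / |CMF|`, reported to one
decimal. Group summaries use the sample (n−1) standard deviation. Quality
stratification puts completeness exactly at the threshold (default 90%)
into the high-quality stratum.

## Statistics

All tests are implemented from their definitions; the suite cross-checks
each against SciPy and against brute-force enumeration oracles.

* **Kruskal–Wallis**: midranks, tie-corrected
  `H/(1 − Σ(t³−t)/(N³−N))`, χ² p-value with g−1 df; for pooled N ≤ 8 the
  p-value comes from full enumeration of all group labelings instead.
* **Rank-sum (Mann–Whitney U)**: exact two-sided p by enumeration when
  the pooled size is ≤ 12 and tie-free (extremeness measured by
  |U − n₁n₂/2|, which matches the symmetric-distribution tail
  convention); otherwise normal approximation with tie-corrected
  variance and continuity correction. Both Kruskal–Wallis and rank-sum
  are reported by the pipeline for the two-group adherence comparison,
  side by side.
* **Fisher's exact (2×2)**: two-sided by the point-probability ordering
  (the R convention): p sums hypergeometric probabilities of all tables
  with the observed margins whose point probability is ≤ the observed
  one, with 1e−7 relative tolerance on the comparison. The sample odds
  ratio is reported, flagged infinite/zero on empty cells.
* **Kendall τ_b**: vectorized O(n²) pair counting with the standard tie
  terms; p from the normal approximation on the tie-corrected variance
  of C − D. The O(n²) memory footprint caps practical use around a few
  thousand observations, which covers the intended cohort sizes.
* **PERMANOVA**: `SS_total = Σ_{i<j} d²_ij / N`, within-group analogue
  per group, pseudo-F as usual; p = (1 + exceedances)/(1 + permutations)
  over seeded label permutations (default 999), or exact enumeration of
  all label permutations for small N. Permutation F-values are computed
  by matrix products over a permutation block, not per-permutation loops.
* No multiple-testing correction is applied anywhere; the pipeline runs
  a small, fixed battery of confirmatory tests and reports each p-value
  raw.

## Ordination and clustering

* **Distances**: Jaccard (`1 − a/(a+b+c)`, joint absences excluded; an
  all-zero pair gets distance 0 with a warning) and binary Euclidean
  (`√hamming`). Both are computed by Gram-matrix algebra and verified
  against `scipy.spatial.distance.pdist`.
* **Ward clustering** uses `scipy.cluster.hierarchy.linkage(…, "ward")`
  — the Lance–Williams update on the input distances (the Ward.D2
  convention), with monotone merge heights. On Jaccard input Ward is a
  heuristic rather than variance-exact, matching common practice. Tie
  handling is SciPy's deterministic nearest-neighbor-chain order.
* **PCA** is the SVD of the column-centered (unscaled) binary matrix;
  centering preserves pairwise differences, so Euclidean distances among
  full-rank scores equal the binary-Euclidean distances to machine
  precision (asserted at 1e−9 in the suite). Axis signs are fixed by
  making each axis's largest-magnitude loading positive. Column scaling
  is deliberately not applied.
* **Logistic PCA** fits natural parameters `Θ = μ + UVᵀ` (per-feature
  offset plus rank-k interaction) minimizing the Bernoulli negative
  log-likelihood `Σ log(1+e^Θ) − X∘Θ`. The logistic loss has curvature
  ≤ 1/4, giving the quadratic majorizer whose minimization step is:
  working response `Z = Θ + 4(X − σ(Θ))`, offset = column means of Z,
  interaction = rank-k truncated SVD of the centered Z. Each step solves
  the majorizer exactly, so the objective is non-increasing — asserted
  per iteration in the suite. Default initialization is the centered-data
  SVD scaled by 4 (a logit-slope heuristic); random initialization is
  available and seeded. Convergence: relative objective change < 1e−6 or
  `max_iter`.

## The synthetic cohort generator

The generator emulates the statistical structure of a two-group screening
campaign, not its biology. Per genome: true completeness
`c ~ Beta(α, β)`; CMF gene j present with probability `c·q_j`
(independent across genes); `Poisson(rate)` decoy genes drawn from a
fixed vocabulary whose keys are disjoint from the catalog, 10% of them
flagged `hypothetical protein` to exercise the certainty filter;
simulated completeness = `clamp(100c + N(0, σ_q), 0, 100)`. One root seed
spawns per-genome streams, so output is byte-identical under a fixed seed
and individual genomes do not depend on generation order.

The `c·q_j` product form is the simplest mechanism that produces both a
completeness gradient in ordination space and heterogeneous per-gene
deficits; it assumes gene losses are independent given completeness,
which real assembly artifacts (operon-level dropouts, GC bias,
phylogenetic correlation) violate. Passing tests therefore demonstrate
that the pipeline recovers the parameters of *this* model, not that real
MAG catalogues behave this way.

### Benchmark conditions and calibration

The default benchmark cohort has 400 isolate-like and 1,000 MAG-like
genomes and a 183-function catalog (44 ribosomal proteins, 20
aminoacyl-tRNA ligases, 20 tRNA isotypes, 3 rRNAs, tmRNA, and 95 further
replication/transcription/translation/metabolism genes). Targets, fixed
once by moment matching and not revisited:

* isolate-like: mean adherence 93.2% with small spread — Beta(85.0, 4.4)
  (E[c] ≈ 0.951, SD ≈ 0.023) and uniform detectability solved from
  `E[adherence] = E[c]·q̄`, giving q ≈ 0.980;
* MAG-like: mean adherence 67.9% with large spread — Beta(10.72, 2.68)
  (E[c] = 0.8, SD ≈ 0.105); a 16S-like key at q = 0.25 (missing in
  ≈ 80%); four hard genes (FtsH-, topoisomerase-4-, dihydrolipoyllysine-
  acetyltransferase- and HisB-like) at q = 0.15 (missing in ≈ 88%);
  40 further genes at q = 0.5 (missing in ≈ 60%), so exactly 45 keys sit
  above the 50%-missing threshold in expectation; remaining detectability
  solved from the group mean, q ≈ 0.974;
* completeness reporting noise σ_q = 6.3 percentage points for the
  MAG-like group, chosen via the bivariate-normal relation
  τ = (2/π)·arcsin(ρ) so that Kendall τ between adherence and simulated
  completeness is ≈ 0.6 (verified by simulation: τ ≈ 0.61 at seed 17);
  2.0 points for the isolate-like group.

Contamination rates default to 3 (isolate-like) and 12 (MAG-like)
expected decoy genes per genome.

The synthetic minimal-genome pair used to exercise CMF *derivation*
carries all 183 catalog functions plus 17 and 34 genome-specific certain
genes and a block of hypothetical calls apiece, so the intersection is
exactly the catalog and the coverage statistic evaluates to 91.0% and
83.9% under the documented denominator. It is a constructed stand-in —
labelled synthetic throughout — not a real genome annotation.

## Problem sizes and determinism

The test suite and the acceptance script run the benchmark cohort at
400 + 1,000 genomes, type-I calibration at 1,000 replicates (two groups
of 20 per replicate), enumeration oracles at pooled N ≤ 8, and the
logistic-PCA monotonicity check at 40×60 for 200 iterations; the full
suite completes in well under a minute. Every stochastic step takes an
explicit seed; the pipeline refuses a config without one, and re-running
an identical config reproduces `summary.json` bit for bit.

## Known limitations

* String-identity matching cannot rescue genes annotated under synonyms
  or split/merged gene calls; a real screen inherits the annotator's
  vocabulary and its version.
* The coverage denominator and the non-filtering of screened genomes are
  conventions; both are configurable and both materially affect absolute
  (not relative) numbers.
* Jaccard + Ward is heuristic (no variance interpretation off Euclidean
  input); PERMANOVA assumes exchangeability under the null, which group-
  specific dispersion differences violate — the benchmark cohort has
  markedly unequal dispersions, so its PERMANOVA p-values should be read
  as detecting *some* location/dispersion difference.
* Logistic PCA's MM scheme trades per-iteration progress for a descent
  guarantee; it can need more iterations than second-order methods.
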