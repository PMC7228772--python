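# Methods

## The measurement being modelled

PhIP-Seq (phage immunoprecipitation sequencing) displays a tiled peptide
representation of the proteome on phage — here 49-amino-acid tiles with
25-AA overlap, i.e. a 24-residue step — incubates the library with serum,
captures antibody-bound phage on protein A/G beads, and sequences the
captured clones. A peptide's read share in a serum IP, compared with its
share in beads-only mock IPs, measures antibody reactivity. The pipeline
consumes the tile × sample count matrix; alignment of raw reads to the oligo
library is upstream and out of scope.

## Enrichment statistic

1. **Normalization.** Each sample column is converted to percentage of total
   reads (sums to 100), removing depth variability.
2. **Gene aggregation.** A gene's value is the **sum** of its member-tile
   percentages — the gene's share of the sample's reads — so gene columns
   still sum to 100. A `max` mode (strongest tile) is available for
   sensitivity analysis; pooling choice is a genuinely open design point and
   sum is the default because it preserves the partition property.
3. **Fold-change.** fold = (value + ε) / (mean over mock-IPs + ε). The
   pseudocount ε is the percentage equivalent of one read at the *median
   mock sequencing depth* (100 / median mock depth); it keeps folds finite
   when the mock background is zero and shrinks low-count noise, while being
   negligible (~1e-4 %) for any well-covered peptide. The background is the
   arithmetic mean of mock percentages; median is available as an option.
   With ε → 0 and positive backgrounds the statistic is scale-free.

## Hit calling

A gene is positive in a sample at fold ≥ 10 (inclusive). Candidate antigens
require ≥ `min_cases` positive case sera (2 for screening against the
literature, 3 for novel-antigen calling) and ≤ `max_controls` (default 0)
positive control sera; mock samples never count, and validation-cohort
samples are excluded from discovery tallies. Ties in every ranking break
alphabetically by gene symbol so outputs are reproducible.

Candidate sets nest as `min_cases` grows. They also nest as the fold
threshold grows **when no control cap applies**; with a finite
`max_controls` the nesting can genuinely break, because raising the
threshold may de-positivize the one control that was excluding a gene. The
property tests check the version that is mathematically true.

For heatmaps, gene rows are z-scored with the sample (n−1) standard
deviation and clustered with distance 1 − Pearson correlation, average
linkage (complete linkage available); column (sample) order comes from the
same distance on the z-scored matrix transposed. Zero-variance rows cannot
be correlated: they get all-zero z-scores, a flag, and are placed last.
Undefined correlations elsewhere (constant columns) are assigned distance 1.
Leaf order is deterministic given input order.

## Tissue-specificity resampling test

Per gene, specificity ratio = max tissue expression / summed expression
(1 = one tissue only; 1/n_tissues = flat). The observed statistic is the
mean ratio of the hit genes present in the expression matrix. The null is
built by drawing gene sets of the same size uniformly **without replacement
from all genes with nonzero total expression, hits included** (no exclusions
are applied because none are implied by the test's design), n_iter = 10,000
by default. The empirical p uses the add-one estimator
p = (1 + #{null ≥ observed}) / (n_iter + 1) — never exactly zero, bounded by
1 — and the test is one-sided for restriction. Hit genes missing from the
matrix reduce both the observed set and the null draw size and are reported
in the result. All-zero rows are dropped with a warning.

## Phenotype association

For each (gene, phenotype) pair, case enrichments with vs without the
phenotype are compared by a two-sided two-sample Kolmogorov–Smirnov test;
because KS depends only on ranks, fold vs log-fold is immaterial. Exact
p-values are used when n_with × n_without ≤ 10,000, the asymptotic
distribution otherwise. Groups smaller than 3 after pairwise dropping of
missing phenotype values yield a missing entry instead of an unstable p.
Direction = mean(with) − mean(without); significant results in the
protective direction (direction ≤ 0, raw p < 0.05) are masked to p = 1,
keeping only disease-elevated signals. No multiple-testing correction is
applied by default; Benjamini–Hochberg is available by flag. Phenotypes
flagged sex-specific restrict the tested population to the relevant sex
when sample sex is available.

## RLBA statistics

antibody index = (mean sample cpm − mean blank cpm) / (mean positive-control
cpm − mean blank cpm). Replicate wells are averaged **before** the formula;
negative indices (noise below blank) are retained. The index is invariant to
affine rescaling of all cpm (instrument gain and offset cancel). Positivity:
index strictly greater than mean + k·SD of the control indices (sample SD,
k = 3 default, per-antigen overrides such as k = 6 for antigens with very
clean control backgrounds). Group separation uses a two-sided Mann–Whitney
U; cross-assay agreement is the Pearson r between antibody index and
PhIP-Seq gene enrichment over paired discovery-cohort samples; dual-antigen
agreement is the fraction of shared samples with equal flags plus the 2×2
table.

## The synthetic-study generator

Purpose: every stage above must be testable with known ground truth, so the
generator emulates a whole study at the discovery design: **39 cases,
28 controls, 17 mock-IPs, 200 genes** (~8 tiles each, so ~1,600 tiles),
1e6 reads per sample.

* **Library.** Protein lengths jitter around the 8-tile target including a
  sub-step remainder, so C-terminus-anchored final tiles are exercised.
  Sequences are uniform random — only coordinates are consumed downstream.
* **Counts.** Tile base abundance is log-normal(0, 1) (the standard
  heavy-tailed model for library representation; it produces realistic
  dropout at finite depth). A serum's two IP/amplification rounds are
  collapsed into one **net multiplicative enrichment factor** applied to the
  antigen's epitope tiles — only the net factor is identifiable from
  post-protocol counts. Each sample is one multinomial draw, so columns sum
  exactly to the depth and enriched mass competes reads away from everything
  else (at 200 genes this renormalization is mild; at very small library
  sizes it can push folds below threshold, which is why unit-scale fixtures
  use 40 genes).
* **Planted truth.** 10 antigens, net factors log-uniform in [30, 300]
  (spanning weak-but-callable to strong responses), epitope fraction 0.75 of
  a protein's tiles (polyclonal sera typically map epitopes across most of
  the protein), 5–15 reactive cases each.
* **Phenotypes.** Each planted antigen links to one manifestation with
  penetrance 0.9 and background rate 0.05; unlinked manifestations fill the
  table to 24 at prevalence 0.3.
* **Expression.** 74 tissues. Restricted genes put 92–98 % of their mass in
  one tissue; broad genes draw uniform(0.6, 1.4) per tissue, so their
  max/sum ratio sits near 1/74.
* **RLBA.** Latent reactivity is a saturating function fold/(fold + 50) of
  the planted enrichment plus N(0, 0.02) jitter; well cpm is the affine
  blank→positive interpolation (blank 250 cpm, positive control 25,000 cpm)
  with N(0, 250) well noise, floored at zero; sera run in duplicate with 4
  blanks and 2 positive-control wells.

All stages draw from child streams of a single seed
(`numpy.random.SeedSequence.spawn`), so a study is a pure function of its
config and bit-reproducible.

**What the generator does not emulate:** sequencing error and alignment
ambiguity, PCR duplicates, inter-round amplification kinetics, epitope
chemistry or antibody affinity, shared reactivity structure between samples
(each antigen's reactive set is independent), and the real proteome's
~20,000-gene scale with isoform redundancy. Passing tests therefore
demonstrate that the statistics recover the planted structure under the
stated noise model — not that the thresholds are optimal for real cohorts.

## Problem sizes used in tests

Recovery, association, and cross-assay checks run 20 seeds of the
39/28/17 × 200-gene design (seconds each). The resampling-calibration check
uses a 200-gene, 30-tissue atlas with 1,000 replicates of n_iter = 1,000,
chosen to estimate the p < 0.05 rate with a 3-SD binomial band of ±0.021.
Unit fixtures use a 40-gene, 6+4+3-sample study.

## Known limitations

* Gene-level pooling by sum makes long genes (more tiles) slightly noisier
  in percentage terms than short ones; the max mode trades that for
  sensitivity to single-tile artifacts.
* The resampling null ignores gene-length and expression-level matching; it
  answers "more restricted than a random gene set", nothing finer.
* KS exact p-values with heavily tied enrichments are conservative.
* The pipeline treats cohort labels as given; it performs no batch
  correction across sequencing runs.
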