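# Methods

`concordx` models the situation where the same RNA isolates are measured
twice: once by whole-transcriptome 3′-tag counting (one read per
transcript, no length bias; "seq") and once by a fixed ~800-gene
hybridization panel with positive/negative control probes and
housekeeping genes ("panel").  The package quantifies how well the two
technologies agree — at the count level, per sample and per gene; at the
effect level, via log2 fold changes; and at the decision level, via the
overlap of differentially-expressed-gene (DEG) sets.

## Synthetic paired-platform studies

Counts for gene *g* in sample *s* on a platform are negative binomial
with mean

    mu_gs = 2^( b_g + beta_g·[s ∈ B] + t_gs + c_g + d_s + e_gs )

and variance `mu + phi·mu²`, where

| term | meaning | default |
|------|---------|---------|
| `b_g` | baseline log2 expression, N(5, 2.5²) | transcriptome-wide spread over ~4 orders of magnitude |
| `beta_g` | true log2 fold change, N(0, lfc_sd²) on a `de_fraction` of genes, exactly 0 elsewhere | `lfc_sd` 1.5, `de_fraction` 0.10 (entity contrast) / 1.0 and 0.04 (stage contrast) |
| `t_gs` | shared biological deviation of sample *s* for gene *g*, N(0, `bio_log2_sd`²) | 1.0 log2 units |
| `c_g` | per-gene platform capture efficiency, drawn once per platform | SD 0.5 |
| `d_s` | per-sample depth / lane effect, per platform | SD 0.25 |
| `e_gs` | per-observation log-normal noise, per platform | SD 0.25 |
| `phi` | NB dispersion | 0.2 (seq), 0.1 (panel) |

`t_gs` is part of the *truth* and is seen identically by both platforms.
It is what makes a gene's movement across samples reproducible between
instruments; without it, a non-DE gene's counts vary across samples only
through platform-specific noise and its cross-platform gene-wise
correlation is ~0 regardless of data quality.  With the defaults, median
gene-wise Pearson/Spearman sits around 0.6–0.7 and sample-wise
Pearson-log around 0.9, the regime reported for FFPE cross-platform
comparisons.  The NB counting noise is relatively larger at low means
(CV² = 1/mu + phi), which by itself produces the observed pattern of
correlation strength growing with expression level.

Two built-in designs mirror the study conditions: an entity contrast
(groups of 15 baseline vs 10, 810 endogenous + 20 housekeeping probes,
9 panel genes absent from the annotation) and a stage contrast (5 vs 5,
780 + 20 probes, 10 missing, weaker biology).  Housekeeping genes are
drawn from non-DE genes only; positive-control probes have fixed means
spanning four orders of magnitude (0.8 … 8×10⁴) scaled by the lane
effect; negative controls are Poisson with mean 2.  The sequencing
matrix covers every simulated gene *except* the panel genes flagged
missing from the annotation (they do not exist for that platform), while
the panel matrix carries all probes.  A single master seed spawns
per-component child seeds (`numpy.random.SeedSequence`), so identical
configuration + seed reproduces a study bitwise.  Platforms support a
`sampling="expected"` mode returning `round(mu)` — the noise-free limit
used for exactness checks.

What the generator does *not* emulate: FFPE chemistry and degradation
gradients, probe cross-hybridization, batch effects beyond a scalar lane
factor, correlated gene modules, and count–quality interactions.  Tests
passing on simulated data therefore show the pipeline's arithmetic and
statistical behaviour under a clean NB world, not the full messiness of
archival tissue.

## Normalization

* **CPM** — counts / library size × 10⁶.
* **TMM** — reference sample chosen by upper-quartile CPM closest to the
  mean; per-sample factor = 2^(weighted trimmed mean of M-values), 30 %
  two-sided trim on M, 5 % on A, delta-method inverse-variance weights,
  zeros in either member excluded, factors centered to geometric mean 1.
  Matches edgeR's `calcNormFactors(method="TMM")` to 1e-6 (tested).
* **RLE** — median over genes of count / geometric-mean reference,
  genes with any zero excluded; the median is taken in linear ratio
  space.  Matches DESeq2's size factors to 1e-6 (tested).
* **Panel two-step** — step 1: scale each sample by (mean over samples
  of the geometric mean of positive controls) / (its own
  positive-control geometric mean); step 2: same with housekeeping genes
  on the step-1 output.  The step-1 lane average uses the *arithmetic*
  mean of per-sample geometric means.  Samples whose factor leaves
  [0.3, 3] (positives) or [0.1, 10] (housekeepers) are flagged with a
  reason, never dropped; the windows are configurable defaults.

All four schemes multiply each sample by one positive scalar, so
within-sample ranks are untouched — sample-wise Spearman against the
other platform is *exactly* identical across none/CPM/TMM/RLE (asserted
as exact equality, not a tolerance).  Sequencing-side factors are
computed on the full gene set before subsetting to panel genes.

## Correlation profiles

Coefficients: Pearson; Pearson on log2(x + pseudocount), default
pseudocount 1, log base 2 (the base only rescales both vectors, Pearson
is invariant — fixed for reproducible intermediates); Spearman with
mid-ranks.  The gene universe of a profile is the intersection of both
matrices, so panel genes missing from the annotation drop out first.
Units with zero variance on either side are reported as undefined (NaN)
with a reason code and counted — never imputed.  Gene-wise profiles need
≥ 3 shared samples, sample-wise ≥ 3 shared genes.

Expression strata are nested gene sets: all, top 90 % and top 50 % by
mean log2 expression, thresholds at the 10th and 50th percentiles
(configurable), computable against either platform's mean expression.
Box summaries use linear-interpolation quartiles and 1.5×IQR whiskers so
they are bit-reproducible.  Correlation strengths are labelled on |r|:
≥ 0.8 very strong, 0.6–0.8 moderately strong, 0.3–0.6 fair, < 0.3 poor.

## Differential expression

Per gene, a two-group NB GLM with log link and per-sample size-factor
offsets, fit by IRLS (tolerance 1e-8, ≤ 100 iterations, linear
predictor clipped at ±30 on the natural-log scale for separated genes).
The dispersion is a pooled within-group method-of-moments estimate,
`phi = Σ(n_k−1)(v_k − m_k) / Σ(n_k−1) m_k²`, floored at 1e-8 — by
design there is no empirical-Bayes moderation across genes, keeping the
engine a documented approximation of the heavyweight tools rather than a
re-implementation.  Because that per-gene dispersion is noisy at small
n, the Wald statistic is referred to a t distribution with n − 2 degrees
of freedom rather than a normal: on null simulations (5 vs 5, phi 0.2)
the normal reference is anticonservative (empirical size ≈ 0.09 at
nominal 0.05) while t(n−2) is calibrated (≈ 0.05, asserted within 3
binomial standard errors).  The baseline group is the lexicographically
first label unless specified, which makes label swapping exactly negate
the log2 fold changes.

Shrinkage is the conjugate normal posterior mean,
`lfc_shrunk = lfc_raw · s²/(s² + se²)`; the automatic prior SD `s` is
the 0.90 quantile of |lfc_raw| over defined genes (floored at 1e-6).
It never changes a sign and shrinks high-variance (low-count) genes
hardest.  BH and BY step-up adjustments are computed in-package so that
undefined p-values (all-zero genes) pass through without counting toward
the number of tests; BY multiplies the BH quantity by the harmonic sum
c(m).  DEG gates are inclusive: padj ≤ 0.05 and |log2FC| ≥ 1.

## Concordance

Annotation overlap reports found/missing panel genes with full-precision
percentages; display rounding is one decimal unless the exact value
needs two (98.75 stays 98.75, 98.9156… becomes 98.9).  Log2FC
concordance (Pearson + Spearman) is computed on shared genes with
defined estimates, for raw and shrunken fold changes.  Direction
classification partitions the shared genes into both_up/both_down,
a_only_*/b_only_*, opposite and not_significant; "opposite" is retained
even though well-behaved data rarely populate it — the partition must be
exhaustive.  The Jaccard index is |A∩B|/|A∪B| with 0 for two empty sets
by convention.  Venn identities (a_only + both = |A|) and
tally-vs-DEG-set reconciliation are asserted in tests.

## Pipeline and QC

Sample gates follow the FFPE RNA-quality rules: keep iff RQN > 4 and
DV200 > 64.5 % (both strict); DV200 classes are > 70 high, 50–70 medium
(both edges medium), < 50 low.  `run_pipeline` chains simulate → QC →
normalize → correlate (both axes, all coefficients, all requested
normalizations; the panel side always two-step normalized, the "none"
variant uses raw sequencing counts) → strata → per-platform DGE (RLE
size factors on the sequencing side, inverted two-step multipliers on
the panel side; all samples are used for both correlation and DGE) →
concordance report, and writes every artifact plus a manifest with
config hash, seed and version.  Outputs are byte-identical across reruns
of the same config + seed.

## Problem sizes and limitations

The default simulated studies run at the full 12 000-gene transcriptome
scale (~10 s end to end); the test suite uses 600–2 000-gene studies.
Known limitations: only two-group designs (no covariates, no
multi-factor contrasts); no independent filtering or outlier replacement
in the DGE engine; RCC support is read-only and validated against
self-generated fixtures; no figure output.
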