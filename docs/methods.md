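# Methods

`xdiverge` implements a cross-species transcriptome-divergence analysis
for two species profiled under a shared stress design — here a
cold-exposure time course (control 28 °C; 8 °C at 0 h, 6 h, 12 h; three
biological replicates per cell) — followed by gene-set and promoter
motif enrichment over the divergent ortholog pairs. This note describes
the statistical models, the defaults and why they were chosen, and what
the synthetic-data generator does and does not emulate.

## Count model and divergence contrast

Counts for gene (or ortholog pair) *g* in sample *i* are modelled as
negative binomial,

    y_gi ~ NB(mu_gi, phi_g),    Var(y) = mu + phi mu^2,
    log mu_gi = log(N_i f_i) + x_i' beta_g,

with `N_i` the library size (column sum), `f_i` a TMM normalization
factor, and a log link. The design is *cell means* over the combined
species:condition factor — one coefficient per species x condition
level (8 levels for the full 2 x 4 design) — fitted per gene by IRLS
with step-halving (tolerance 1e-8 on the deviance change, at most 50
iterations; the deviance is non-increasing across iterations by
construction). All genes are fitted simultaneously with batched linear
algebra; genes with all-zero counts are flagged and excluded from
testing and from the multiple-testing denominator.

Expression divergence of an ortholog pair at a timepoint is the
species-by-cold interaction, tested with the difference-of-differences
contrast on the cell-means coefficients:

    c'beta = (B:tp − B:ctl) − (A:tp − A:ctl).

Normalizing each species' cold response to its own control is done
entirely by this contrast; counts are never pre-divided. The sign
convention is fixed: positive = larger cold response in species B (the
second species); swapping species labels flips the sign exactly.
Inference is a likelihood-ratio test (full vs contrast-constrained
model, chi-square with 1 df), not a quasi-likelihood F-test. P-values
are Benjamini–Hochberg adjusted within each timepoint's contrast
(configurable to pooled adjustment), and a pair is called divergently
expressed when |log2 contrast| > 1 **and** FDR < 0.05, both strict. The
same engine and rule serve within-species differential expression
(condition vs control).

Cross-species caveat: each sample keeps its own species' effective
library size as offset (TMM is computed within each species' sample
block); no gene-length or annotation-depth correction across species is
applied, so absolute cross-species level differences are absorbed by
the per-gene species coefficient and only the *response* difference is
tested.

## Dispersion

`phi` is estimated by maximizing the Cox–Reid adjusted profile
likelihood, `APL_g(phi) = ll_g(beta_hat(phi)) − ½ log det(X'WX)`.
Default is a single **common** dispersion (bounded scalar optimization
on log phi, returning 0 when the boundary fit is Poisson-like); an
optional **tagwise** mode maximizes a weighted likelihood
`APL_g + (prior_df / residual_df) · mean-APL` on a phi grid around the
common value with quadratic interpolation, shrinking gene-wise
estimates toward the common one (default prior_df = 10). Numerical
equality with any particular edgeR release is not targeted; parameter
recovery is verified by simulation (true phi = 0.1 recovered within
[0.07, 0.13] at 2000 genes x 6 samples) and, for TMM, against a frozen
edgeR reference value on a fixed matrix.

## TMM normalization

Factors use the trimmed mean of M-values against a reference column
(the sample whose 0.75 count-fraction quantile is closest to the mean):
genes with zero counts in either sample are dropped, the log2 ratios are
double-trimmed (30% on M, 5% on A, each side), and the surviving
M-values averaged with inverse delta-method variances. Factors are
rescaled to geometric mean 1; a pure sequencing-depth difference yields
factors of exactly 1.

## Gene-set enrichment

Over-representation of a term among divergent pairs uses the upper-tail
hypergeometric probability including the observed count,
`p = Σ_{j≥i} C(M,j) C(N−M,n−j) / C(N,n)`. The tail is evaluated through
the survival function (with a log-space summation fallback when it
underflows); agreement with exact rational enumeration is tested for
every (N, n, M, i) with N ≤ 60. The default universe is the set of
tested ortholog pairs, not the whole genome (configurable). Terms are
flagged at raw p < 0.05 — no multiplicity adjustment by default,
mirroring how such screens are conventionally reported — with BH
adjustment available by flag. Gene sets are used as given: no ancestor
propagation over the ontology graph. KEGG-style pathway sets run
through the identical machinery.

## Promoters and PWM scanning

The TSS is the first base of the 5′ UTR of a gene's canonical
transcript (minus strand: the maximum transcript coordinate); the
promoter is the 1 kb immediately upstream in gene orientation,
excluding the TSS base, truncated at contig edges. Coordinates are
0-based half-open internally, BED dialect on disk.

A position frequency matrix is converted to log2 log-odds against a
0-order background with a background-distributed pseudocount
(default 0.1):

    PWM[x][j] = log2((count[x][j] + 0.1 b_x) / (total_j + 0.1) / b_x).

Scores are discretized (granularity 1e-3 log2 units) and the exact
distribution of a background-random k-mer's score is computed by
dynamic programming over columns; window scores use the same integer
bins, so scan P-values are exactly the DP tail. Both strands of each
promoter are scanned (the reverse strand by scoring with the
reverse-complemented matrix; its null distribution is recomputed, and
coincides with the forward one because the default background is
complement-symmetrized — the appropriate null for double-strand
scanning). Windows containing N are skipped. A window is a hit when
P(score ≥ s) < 1e-4 (strict). The background defaults to the scanned
promoter set's own composition, configurable to uniform. Because the
attainable P-values form a step function, the realized null hit rate is
the largest attainable tail value below the threshold — very close to
the nominal threshold for information-rich motifs, below it for short
or degenerate ones.

## TFBS enrichment

An ortholog pair "contains" a motif when at least one hit passed the
threshold in either species' promoter. Within a scope gene set (an
input list; e.g. the apoptosis-regulation orthologues), presence is
cross-tabulated against divergence and tested with the two-sided
Fisher exact test by the point-probability rule, computed by one
vectorized hypergeometric-pmf pass over the conditional support with a
relative tie tolerance of 1e-12 (for totals ≤ 40, distinct support
probabilities differ by at least ~7e-12 relatively, so ties are decided
exactly). The reported odds ratio is the conditional maximum-likelihood
estimate under the noncentral hypergeometric model (via scipy), the
estimator standard exact-test implementations print; it shrinks toward
1 relative to the sample cross-product ratio. Zero-margin tables return
p = 1 with an undefined (NaN) odds ratio. Raw alpha = 0.05 per motif by
default, BH by flag.

TF-catalog helpers flag a transcription factor as apoptosis-related
when any of its GO term names contains the literal substring
"apoptosis" or "apoptotic" (case-insensitive; "programmed cell death"
does not match). Subnetwork extraction induces the subgraph of a
user-supplied interaction edge list (physical / co-localization /
genetic) on the query TFs plus declared intermediates and reports the
fraction of query nodes in the largest connected component.

## Synthetic data generator

The generator emulates the emulated study design so every stage is
testable without downloads: 2 species x {28C, 8C_0h, 8C_6h, 8C_12h} x 3
replicates of NB counts with log-normal baseline means (median 200,
log-sd 1.0), a per-gene species offset (log-sd 0.3) and a shared
per-gene cold response (log-sd 0.5), common dispersion 0.05, library
sizes jittered uniformly in [0.7, 1.3], and a planted species-by-cold
interaction of |log2| = 2.5 in 10% of pairs (defaults; all
configurable). Promoters are i.i.d. background sequence (A/T 0.3, C/G
0.2) with one sampled motif instance planted in one randomly chosen
species' promoter at probability 0.6 (divergent pairs) vs 0.1
(non-divergent). Annotations contain log-uniform background terms
(10–300 members) plus planted terms of 50 members sampled at 8x odds on
divergent pairs. One global seed expands into per-component seeds via
fixed spawn keys (counts 0, promoters 1, annotation 2), so adding a
generator never perturbs existing streams, and identical seeds give
byte-identical files.

What it does **not** emulate: gene-length and GC biases, correlated
genes/pathway structure, sample outliers or batch effects, dinucleotide
promoter composition, clustered or overlapping motif sites, and
annotation incompleteness. Passing recovery tests therefore demonstrate
correctness of the estimators and calibration under the assumed model,
not robustness to those real-data complications.

For the end-to-end TFBS scenario (200 ortholog pairs, planting 60%/10%)
the divergent fraction is set to 24/65 ≈ 0.37, the composition of the
published apoptosis-regulation scope (24 divergent vs 41 non-divergent
orthologues).

## Numerical choices and degenerate inputs

- IRLS: linear predictor clamped at ±40; ridge 1e-10 on the normal
  equations; step-halving (≤12 halvings) enforces monotone deviance.
- Dispersion search bounded to [1e-6, 10]; boundary minima report 0.
- All-zero genes: flagged, NaN statistics, excluded from BH's m.
- BH: NaN p-values propagate and are excluded from m.
- PWM: −inf log-odds (zero count, zero pseudocount) floored at −64;
  sequences shorter than the motif yield no hits; empty support guards
  return p = 1.
- Fisher/hypergeometric degenerate margins return p = 1 (OR NaN).
- Problem sizes in the acceptance checks (1,000 pairs for divergence
  calibration, 200 seeds x 200 pairs for TFBS, 50 seeds for GO) are the
  package's chosen desk-scale study conditions; genome-scale counts
  from the original study require its sequencing data and are out of
  scope.

## Known limitations

- Exact numerical equality with specific edgeR/FIMO releases is a
  non-goal; semantics (models, rules, thresholds) are matched instead.
- The conditional-MLE odds ratio depends slightly (~1e-4) on the
  root-finder; printed 2-decimal values can differ in the last digit at
  rounding knife-edges.
- One-to-one orthologs only; no phylogenetic normalization of
  expression levels; no enhancer/distal element analysis; motif
  scanning only (no de novo discovery).
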