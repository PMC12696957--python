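# Methods

`methylmorph` re-implements, as a tested pipeline over fully synthetic
data, the developmental whole-genome bisulfite (WGBS) methylation
analysis used for holometabolous insects such as the jewel wasp: five
developmental stages (embryo, larva, prepupa, pupa, adult), three
replicates each, a sparse CpG methylome, and RNA counts modelled against
methylation. This note describes the statistical procedures, the
synthetic-data model that stands in for the sequencing data, the
numerical choices, and what the tests do and do not demonstrate.

## Methylation calling

**Non-conversion calibration.** Bisulfite converts unmethylated
cytosines to uracil; the fraction that escapes conversion appears
falsely methylated. An unmethylated lambda-phage spike estimates this
false-positive rate as the pooled methylated fraction over *all* lambda
cytosines, regardless of context — the whole spike is unmethylated, so
every C informs the error rate. A zero estimate is replaced by the
pseudo-rate 1/(total coverage + 1) (with a warning) because a binomial
test at success probability 0 is degenerate. The estimate's standard
error is the usual binomial `sqrt(r(1-r)/N)`.

**Destranding.** The two cytosines of a CpG dyad (plus-strand C at
position *i*, minus-strand C at *i*+1) are pooled into one record
reported at *i*, doubling effective coverage. Counts are conserved
exactly; unpaired strand records pass through, and a minus-strand
record with no dyad in the genome is kept as a singleton with a
warning. All public coordinates are 1-based inclusive.

**Binomial test.** After filtering to coverage ≥ 10 reads (the field's
customary minimum for per-CpG estimates), each site is tested against
Binomial(coverage, non-conversion rate). The test is one-sided
(upper tail): genuine methylation can only inflate the methylated count
above the error rate. P-values are corrected by Benjamini–Hochberg
across all tested sites; a site is *methylated* iff q < 0.05. Because
the binomial null is discrete, realized false-discovery proportions run
below the nominal level; the suite checks empirical FDR ≤ 0.075 over 20
simulation seeds as a guard band for that discreteness.

For the per-stage calling track, replicate reports are pooled
(count-summed) before destranding, mirroring the common practice of
merging replicates for a per-stage methylome overview; differential
analysis (below) keeps replicates separate.

**Feature assignment and aggregation.** Sites are assigned one category
with precedence exon > intron > promoter > intergenic; *intron* means
inside a gene body but outside its exons, and *promoter* means within
1,000 bp upstream of a transcription start site (strand-aware) while
outside every gene body. The promoter window is configurable; 1 kb is a
conventional insect-genome default, chosen here because compact genomes
have short intergenic spans. Gene-level methylation is the
coverage-weighted percentage 100·Σmeth/Σcov over CpGs in the gene body,
and genes are binned into the standard four classes — unmethylated
[0, 0.5), low [0.5, 30), medium [30, 70), high [70, 100] — with
lower-inclusive boundaries (the printed class bounds touch, so a
deterministic assignment rule is needed; lower-inclusive is the
convention adopted throughout). Exon-rank profiles average site-level
percentages per rank, with exon ranks always recomputed from
coordinates in transcript orientation rather than trusted from
annotation attributes.

## Differential methylation

Each CpG covered ≥ 10× in every replicate of both stages is tested by a
per-site logistic regression on replicate-level (methylated, coverage)
observations: logit(π) = β₀ + β₁·stage, fitted by IRLS, with a
likelihood-ratio chi-square (1 df) against the intercept-only null.
With one replicate per group this reduces exactly to the 2×2 G-test,
which the test suite exploits as a hand-computed oracle. The LR test
was preferred over a Wald test for its stability at small counts; no
overdispersion correction is applied. Degenerate sites (all-zero or
all-full in both groups) get p = 1; if IRLS fails outright the site
falls back to a pooled 2×2 chi-square with a warning. Under complete
separation the coefficients diverge but the deviance — and hence the LR
statistic — converges, so no penalization is needed.

A differentially methylated site (DMS) requires p < 0.0125 *and* a
pooled methylation difference strictly exceeding 10 percentage points.
The 0.0125 cutoff is 0.05 Bonferroni-corrected across the four
consecutive stage transitions; both thresholds are parameters.
Direction (hypermethylated in stage 1 vs stage 2) follows the sign of
the difference.

"Consecutive" DMS are maximal runs of ≥ 2 significant sites adjacent in
the position-sorted list of *tested* (coverage-filtered) CpGs of one
chromosome — adjacency among tested sites, not genomic base-pair
adjacency, since untested sites carry no evidence either way. Runs
never span chromosomes; each run is annotated with the gene whose TSS
is nearest to the run's first position. TSS distances use absolute
genomic distance on the same chromosome, ties broken toward the
lexicographically lower gene id for determinism.

Sample structure is summarised by PCA of the samples × sites
methylation-percentage matrix (sites covered in all samples), column-
centered, via SVD; scores are U·S and variance fractions come from the
squared singular values.

## K-mer enrichment

The CpG-centered k-mer of a site is the plus-strand window of even
length k whose central two bases are the dyad's C and G (so k = 6 gives
two flanking bases each side); windows off the chromosome end or
containing non-ACGT bases are dropped. Foreground sites (default: CpGs
methylated in every stage) are compared against the complement of the
tested-CpG universe. Per k-mer: fold change of per-site rates, its
log2, the Haldane–Anscombe odds ratio (0.5 added to each cell of the
2×2 table, so it stays defined at zero cells), the two-sided Fisher
exact p (conventional definition: sum of probabilities of tables no
more probable than the observed one), and BH q across all k-mers
tested. Reverse-complement contexts are not collapsed. Swapping
foreground and background inverts fold and odds ratio and leaves p
unchanged, which the suite checks as a property.

## Expression models

**Normalization.** Median-of-ratios size factors (median over
all-sample-nonzero genes of count/geometric-mean, computed in linear
space), plain FPM (columns scaled to 10⁶; a robust variant divides by a
size-factor-scaled effective library size), and per-gene log2 fold
changes with pseudocount 1 on mean normalized counts (the pseudocount
guards against log of zero and makes the LFC antisymmetric in the two
stages).

**Model families.** Count responses (gene counts or exon counts against
methylation percentage or methylation class, each crossed with stage)
use a quasi-Poisson GLM: log link, IRLS to convergence (relative
deviance change < 1e-8, ≤ 100 iterations), Pearson-estimated
dispersion, and a model test equal to the dispersion-scaled deviance
difference against the intercept-only null, referred to chi-square on
the model df. LFC responses (against number of DMS, TSS distance,
transcription-factor identity, or consecutive-run counts, each crossed
with the pairwise comparison) use Gaussian least squares; the model
chi-square is the residual-sum difference scaled by the full model's
mean squared error. Goodness of fit is reported as deviance explained,
pseudo-R² = 100·(1 − D_full/D_null), which is 0 under the null, 100 at
saturation, and invariant to affine rescaling of continuous predictors.
Categorical variables are dummy-coded against the alphabetically first
level; this changes coefficient labels, not model tests.

**Stage contrasts.** Expression of individual genes across stages
(e.g. methylation-machinery genes) is analysed with the full-
interaction linear model counts ~ stage × gene in cell-mean form:
each contrast is a difference of stage means within one gene, its
standard error uses the pooled residual variance across all cells, t is
referred to the residual df, unadjusted — the estimated-marginal-means
construction for a balanced design.

**DMS/expression join.** The fraction of genes downstream of
significant DMS that are differentially expressed uses the nearest-TSS
gene as "downstream" and a deliberately plain DE screen (per-gene
pooled t on log2 normalized counts, p < 0.05); the screen's only role
is labelling genes for the join, and its threshold is a parameter.

## Synthetic data model

The generator is the package's study system, with ground truth
recorded for every estimand.

* **Genome**: i.i.d. bases at a specified GC fraction (default 0.4,
  insect-like), 1–2 chromosomes of tens of kb for the desk-scale study;
  genes of 0.9–2.4 kb with 2–6 exons (blocks ≥ 60 bp) packed left to
  right with random gaps, random strand. Infeasible packings raise.
* **Methylome**: an always-methylated core (default 1% of CpGs,
  matching the ~1% genome-wide methylation typical of hymenopteran
  methylomes) plus small disjoint stage-unique sets (default 0.2% per
  stage). The first stage's unique set is 3× larger, so the
  embryo→larva transition carries the largest differential set, echoing
  the embryonic demethylation wave this kind of study observes. True
  levels are 0.9 at methylated sites and 0 elsewhere; a `meth_level`
  parameter lowers the planted level for power studies at smaller
  deltas. Core sites are drawn so one chosen CpG-centered 6-mer
  (default TACGTA) occurs at a requested foreground/background rate
  ratio (default 3), planted exactly up to integer rounding by
  stratified sampling.
* **Bisulfite counts**: per-strand coverage ~ Poisson(cov/2) over each
  dyad (default mean dyad coverage 30), methylated reads ~
  Binomial(cov, level + (1−level)·ε) with non-conversion ε = 0.005 —
  the standard additive bisulfite error model. The lambda spike is a
  separate 20 kb random chromosome at level 0 everywhere (every C,
  both strands, all contexts), giving ~3×10⁵ calls at coverage 30 and
  hence a calibration SE near 1.3×10⁻⁴.
* **RNA counts**: log μ = β₀ + stage offset + β₁·(gene methylation %),
  with negative-binomial noise (gamma–Poisson, default dispersion 0.1;
  dispersion → 0 recovers Poisson) and exon counts partitioned
  multinomially by exon length. Default coupling β₁ = 0.02 per
  percentage point gives the count GLMs a recoverable slope. A separate
  helper generates gene × comparison LFC tables linear in the number of
  DMS for the Gaussian models.

What the generator does *not* emulate: read-level artefacts (mapping
bias, PCR duplicates, sequencing error beyond non-conversion),
hemimethylation, overdispersed or position-correlated coverage,
spatially clustered methylation, hydroxymethylation, and any
methylation–expression coupling more complex than a log-linear slope.
Passing tests therefore demonstrate the *procedures* are implemented
correctly and recover known truth under idealized sampling — not that
real libraries satisfy these assumptions.

## Problem sizes and numerical choices

The default desk-scale study uses 1–2 chromosomes × 20–50 kb (one to
four thousand CpG dyads), 16 genes, coverage 30, three replicates —
small enough that the complete pipeline runs in seconds while every
planted signal remains detectable. Dedicated recovery studies scale
single axes up: ~10,000 CpGs with a 1,000-site foreground for k-mer
fold recovery, 500 genes for GLM slope recovery. Binomial tails use the
survival function directly (no normal approximation); logistic IRLS
stops on relative deviance change ≤ 1e-10 (≤ 50 iterations); Fisher
tests use exact hypergeometric enumeration via SciPy; PCA centers but
does not scale, since all columns share the percentage unit.

## Known limitations

* The per-site logistic test ignores replicate overdispersion; with
  genuinely variable replicates its p-values are anticonservative (a
  beta-binomial model is out of scope).
* The stratified k-mer planting controls one context's rate ratio;
  other contexts shift slightly in compensation.
* Exon-level methylation models reuse the gene-level machinery on exon
  units; no exon-usage testing is attempted.
* The DE screen in the DMS join is a labelling device, not a
  replacement for a shrinkage-based differential-expression method.
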