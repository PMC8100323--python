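# Methods

## Study design being modelled

Two oyster populations — a thermotolerance-selected line and an
unselected control — are compared on three layers: genomic structure
(pooled whole-genome resequencing of larvae, one DNA pool per
population), constitutive gene expression (larval RNA-seq, three
replicates per group), and organismal physiology (adult respirometry and
field survival).  The molecular goal is the set of genes differentiated
in *both* structure and expression; adult qPCR around a heat-shock time
course then validates candidates and links genotypes to expression.

## Pooled-sequencing divergence (ED)

Allele frequencies in each pool are plug-in estimates from read depths:
`f(a,p) = AD(a,p) / Σ_a AD(a,p)`.  The per-SNP statistic is the
Euclidean distance between the two pools' frequency vectors; for a
biallelic site `ED = √2·|Δf|`, bounded by `√2`.  Design choices:

- **Screening**: sites with ED < 0.3 are removed; ED exactly 0.3 is
  retained (the removal rule is a strict inequality).
- **Outliers**: a site is an outlier when its ED reaches the
  `ceil(q·n)`-th largest value of the chosen universe (default
  q = 0.05), ties at the cutoff all included.  The universe is the
  post-screen record set by default; `universe="all_snps"` takes the
  quantile over every scanned site, which is the scale the analysis
  drivers use (a 5% slice of all sites, then intersected with the
  retained set).
- **Raw ED**, no fourth-power transform and no windowing/smoothing:
  the screening threshold and the published per-SNP values are on the
  raw scale, and the scan is strictly per-site.
- **Depth filter**: sites where either pool has total depth below
  `min_depth` (default 10) are excluded — pooled frequencies at lower
  depth are too noisy to rank.  This is an addition on top of the
  screening rule, exposed as a flag.
- **Multiallelic sites** are handled by the general vector formula.

At 82× per pool, binomial sampling alone essentially never lifts a
neutral site over ED = 0.3 (measured retained fraction ≈ 0.003 at
n = 5000), so the screen is a strong selector: with a true frequency
shift of 0.5 the ED ranking separates selected from neutral loci with
AUC ≈ 0.97.

## Variant functional classification

Gene models come from GFF3 (union of exons across isoforms; the longest
CDS for coding calls).  A variant gets exactly one class by precedence
**CDS > non-coding exon > intron > upstream > downstream > intergenic**;
among genes offering the same class the nearest TSS wins, with the gene
id as a deterministic final tie-break.  Upstream/downstream are
strand-aware windows (default 3000 bp each side — wide enough to cover a
validated regulatory SNP sitting 2.1–2.2 kb above a TSS; the windows are
flags because no canonical value exists).  CDS substitutions are
classified synonymous/non-synonymous by translating the reference and
alternate codons in the spliced CDS frame; for multiallelic sites the
variant is non-synonymous if any alternate changes the protein.  The
variant's stated reference allele is checked against the genome and a
mismatch is an error, not a silent skip.  Coordinates are 1-based
inclusive externally (GFF3/VCF convention), 0-based half-open inside the
interval trees.

## Read QC

Three removal rules: adaptor (caller-set flag or literal substring
match — no fuzzy matching), N fraction > 10%, and Phred ≤ 10 at > 50% of
bases.  Boundaries are strict: a 100-bp read with exactly 10 Ns or
exactly 50 low-quality bases passes.  The rules are per-read, so the
kept set is independent of stream order.

## Differential expression

Median-of-ratios size factors (the factor of a sample is the median over
all-sample-expressed genes of its count divided by the gene's geometric
mean), log2(normalised + 1) transform, and a per-gene two-sample test
with Benjamini–Hochberg adjustment.  The log2 fold change is computed
from group means of normalised counts with a 0.5 pseudocount to avoid
log 0.  A gene is called up/down only when adjusted p < α (default 0.05)
and |log2FC| ≥ 1.

The default test is a **moderated t**: per-gene pooled variances are
shrunk toward a scaled-F prior fitted across genes by matching the
digamma/trigamma moments of log s², and the t statistic uses the
posterior variance with `d0 + (n−2)` degrees of freedom.  This choice is
forced by the design: with three replicates per group a per-gene
variance has 4 degrees of freedom, and an unmoderated t cannot produce
p-values small enough for any gene to survive FDR control — measured on
synthetic data, a plain Welch t called ~14% of true 4-fold changes while
the moderated t called essentially all of them with empirical FDR ≈ 1%
and a null call rate far below α.  A plain Welch t remains available
(`method="welch"`) for designs with real replication.  The moderation
assumes variances are exchangeable across genes after the log
transform; strongly mean-dependent dispersion would argue for a full NB
model instead.

## qPCR relative quantification

Livak's method with amplification efficiency fixed at 2:
ΔCt = Ct(target) − Ct(reference), ΔΔCt = ΔCt − calibrator, RQ = 2^−ΔΔCt,
so log2 RQ = −ΔΔCt exactly.  The calibrator is the control group's
*mean* ΔCt for the same gene and timepoint (median available by flag);
the control group therefore self-calibrates to geometric-mean RQ 1.  A
second mode calibrates against each group's own 0-h ΔCt, expressing
induction relative to the pre-shock state — that is the mode used for
the plasticity range (max − min of per-timepoint mean RQ), since
induction plasticity is a within-group notion.  Group comparisons of
basal RQ are Welch t-tests on log2 RQ; genotype–expression association
is a Kruskal–Wallis omnibus plus pairwise Mann–Whitney with BH, chosen
because genotype class sizes from field genotyping are small and
unbalanced (classes under 3 samples are dropped with a warning).

## Physiology

Respiration rate is the negated OLS slope of O2 (mg/mL) on time,
reported per hour; R² and residual SD are returned as diagnostics, and a
constant trace yields rate 0 with a degenerate-fit flag rather than an
undefined R².  No per-individual normalisation is applied by default —
the published normalisation is not specified, so any divisor (e.g.
tissue mass) is the caller's column, and temperature is a grouping
label only.  Survival is a per-cage percentage at a requested day, with
group means ± SE over cages and a Welch t-test; the recovery-period rate
after acute heat shock is a simple percentage.

## Synthetic data

Every generator is a pure function of (config, seed) using per-stream
`numpy` Generators, so outputs are byte-identical across reruns and one
stage's draw count cannot perturb another's.  Defaults are the study's
conditions: 82× mean pool depth (Poisson per site, floor 1), 3 vs 3
RNA-seq replicates, O2 sampled every 3 s for 1.5 h (1801 points),
generating respiration rates 0.0012 vs 0.0006 mg/mL/h, survival
probabilities 0.73 vs 0.62 over 3 cages × 100 animals, and heat-shock
time points 0/12/24 h.  Where the study fixes no value we chose once:
neutral allele frequencies Uniform(0.05, 0.95) (keeps ED defined and
non-degenerate), 5% of SNPs selected with a pool-1 frequency shift of
0.5 (clamped to [0,1]), negative-binomial counts with dispersion 0.05
and lognormal library factors (σ = 0.15), qPCR noise 0.3 cycles around a
reference gene at ~20 cycles, trace noise 1e-4 mg/mL, 40 genes of
1.2–3.6 kb with 1–4 exons on mixed strands separated by ≥7 kb so that
upstream/downstream/intergenic zones all exist on a 2 × 300 kb genome.
Truth tables (selected SNP ids, true DE genes with signed log2FC) are
written as sidecar TSVs for recovery tests.

What the generator deliberately does **not** model: linkage
disequilibrium between SNPs, read-level error profiles or indels,
mean-dependent NB dispersion trends, mortality clustering within cages,
or drift between the pools beyond the imposed shift.  Passing recovery
tests therefore show the estimators are correct under the assumed
sampling models, not that the pipeline is robust to those real-data
complications.

## Numerical notes

- ED values from the vectorised norm and a scalar reimplementation can
  differ in the last ulp (summation order); oracle tests compare
  retention decisions exactly and values at 1e-12.
- The trigamma inversion in the variance squeeze uses Newton iteration
  from the asymptotic start `x ≈ 0.5 + 1/target`; when the observed
  log-variance spread is no wider than chi-square noise the prior
  degrees of freedom are infinite and the posterior variance is the
  common prior value.
- BH adjustment and all tests treat zero-variance genes as p = 1 (no
  call) rather than NaN.
- Pipeline outputs are hashed (SHA-256) into a manifest; stage functions
  are pure in (inputs, parameters, seed), which the determinism tests
  assert byte-for-byte.

## Problem sizes

Tests and the acceptance script simulate at 400–10,000 SNPs, 15–500
genes, 2 × 120–300 kb genomes, 20 subjects/traces and 20 seeds for
stochastic recovery checks — sizes chosen so each property is measured
with comfortable statistical margin while the whole suite stays quick to
iterate on.
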