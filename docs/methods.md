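# Methods

This note records the models and procedures the package implements, the
defaults and why they were chosen, what the synthetic-cohort generator does
and does not emulate, and the numerical decisions a maintainer would want
written down.

## Data model and conventions

Small variants carry 1-based positions and are classified purely by allele
lengths: SNV (1/1), MNV (k/k, k>1), INS/DEL otherwise. Regions are 0-based
half-open, and all interval arithmetic is half-open; a mutation at a region's
end coordinate is outside it. Structural variants are typed DEL/DUP/INV/TRA
with 1-based inclusive spans. Alleles are stored as given; strand handling
happens only in channel counting, where purine-centered substitutions are
reverse-complemented onto the pyrimidine strand (96 trinucleotide-context
channels) and doublet substitutions are collapsed onto the canonical
10-reference-doublet set (78 channels). MNVs longer than 2 bp contribute to
neither channel matrix; they are returned in a residual report, and to the
mutation burden. Multi-allelic VCF rows are split into one record per
alternate allele.

## Signature refitting

Per sample, exposures solve min‖R·e − c‖₂ subject to e ≥ 0 (scipy NNLS),
where R holds the reference profiles column-normalized to 1 and c the
sample's channel counts; relative contributions are e/Σe and a reconstruction
cosine is reported per sample. Zero-mutation samples yield an all-zero row,
flagged rather than failed, and are excluded from dominant-signature
denominators and from clustering. Refitting against a fixed reference is
deliberately the only attribution mechanism (no de novo factorization and no
cosine-assignment heuristics): with a full-rank reference and enough
mutations the NNLS solution is unique, which is what makes the recovery
suite's ≥0.99 cosine criterion meaningful.

Dominant signatures require a relative contribution of at least 0.10 in at
least 10 samples (both thresholds inclusive). The clustering signature set is
the union of the dominant set, an externally curated list, and any signature
exceeding 0.25 (strict) in at least one sample. Samples are clustered on
median-centered contributions — centering after signature selection — with
distance 1 − Pearson and average linkage (Euclidean/Ward available), cut into
k = 6 flat clusters by default. Zero-variance rows get a deterministic
distance rule (identical constants at 0, otherwise 1) so degenerate inputs
cluster reproducibly; k caps the number of flat clusters rather than
guaranteeing it. TMB is (SNV + MNV + indel)/Mb with a strictly-greater-than-10
high-burden flag; the denominator defaults to the simulated genome's size in
simulations and should be set to the callable genome size (≈2859 Mb for
GRCh37) on real data.

## Kataegis

Only SNVs enter the intermutation-distance (IMD) series; duplicate positions
collapse, and the first SNV of a chromosome has no IMD of its own. Each
series' log₁₀ IMDs are standardized and segmented by the exact
dynamic-programming minimizer of Σ within-segment SSE + γ·#segments; the DP
is exact (verified against exhaustive enumeration for short series), segments
may contain a single IMD, and `min_points` is the minimal series length worth
segmenting. A segment is called kataegis when it spans ≥5 SNVs with mean
IMD ≤ 2 kb (a strict mode requires every IMD ≤ 2 kb); adjacent called
segments merge into one region, and per-sample region counts are reported.

The penalty γ has no published value; it was calibrated once on the synthetic
suites to γ = 1.0 on standardized values. The choice is driven by a specific
failure mode: with a large γ, a focus of ~6 SNVs absorbs one adjacent
moderate (10–50 kb) gap — splitting it off saves less standardized SSE than γ
— and the arithmetic-mean IMD then creeps over 2 kb. At γ = 1.0 injected foci
(6 SNVs, 500 bp spacing, 1 SNV/Mb background) are recovered in 100/100 seeds
across independent replications, while null series (uniform positions) yield
calls in ≤1/100 seeds. Low γ over-segments flat background series, which is
harmless here because specificity is carried by the ≥5-SNV/≤2-kb calling
filter, not by the segmentation.

## Noncoding driver scan

For every region the cohort-wide mutation rate is total events divided by
region size (events, not mutated samples). A noncoding gene is tested only if
recurrent — mutated in at least 5% of samples — and its baseline is the set
of nonannotated regions larger than 1 kb (strict) intersecting a 2 Mb window
centered on the gene (±1 Mb from its boundaries, truncated at chromosome
ends). The test is a one-sided one-sample Wilcoxon signed-rank of the
baseline rates against the gene's rate as hypothesized center (alternative:
baselines below the gene), exact when ≤25 untied differences and a normal
approximation with continuity correction otherwise; zero differences are
dropped, zero-rate baselines retained. Hochberg's step-up adjusts across
tested genes; genes without qualifying baselines are reported untested.

**Known limitation (anticonservatism).** The gene's rate is itself a noisy
estimate — for a 3–9 kb gene at cohort rates it rests on a handful of Poisson
counts — and it is the *shared* center for all baseline differences: an
upward fluctuation of the gene flips every sign at once, and the recurrence
filter preferentially admits upward-fluctuated genes. Under a uniform-rate
null this procedure therefore rejects far above nominal level (the acceptance
script measures the empirical type-I rate; at the default study design it is
an order of magnitude above 0.05, and even an infinitely precise gene rate
would leave residual inflation from the skew of Poisson rate estimates).
This is a property of the procedure, not of the implementation; adjusted
p-values from this scan should be read as enrichment rankings, not calibrated
error rates. Planted 10× drivers are nevertheless detected at adjusted
p < 0.05 in ≥95% of simulated cohorts because the effect dwarfs the noise.

## MSI-prone counting and enrichment

Mononucleotide stretches are maximal single-base runs of length 6–13 counted
within exons (a junction breaks a run; non-ACGT characters break runs; case
is ignored). Runs of 14+ are deliberately not counted by the stretch counter
— they belong to the annotated-repeat input — and a gene's MSI-prone total is
repeats + stretches. The matched-control sign test compares a gene's MSI-
sample mutation frequency with those of all other genes whose MSI-prone total
lies within ±10%: p = P(Bin(n_eff, ½) ≥ k) with k the controls strictly below
the observed frequency and ties excluded; the binomial tail is evaluated in
exact integer arithmetic up to n_eff = 64. An empty control pool yields an
explicit "no reliable control distribution" flag. The high-burden cluster
association combines a two-sided Fisher exact test (Hochberg-adjusted) with a
permutation test that redraws the gene's mutated-sample set without
replacement with probability proportional to TMB (Gumbel top-k sampling),
p = (1 + #{overlap ≥ observed})/(n_perm + 1) with n_perm = 10,000; with equal
weights this null reduces exactly to the hypergeometric tail, which is the
oracle used in testing. A gene is reported when both adjusted Fisher p and
permutation p fall below 0.05.

## Cohort statistics

Two-sided Fisher exact p sums all tables with the observed margins whose
point probability does not exceed the observed one; a zero margin returns
p = 1 with a flag. Hochberg's step-up is adjusted(i) = min over j ≥ i of
(m−j+1)·p(j), capped at 1 (note it is **not** idempotent off its fixed
points). Group comparisons use Mann–Whitney U (exact for combined n ≤ 20
without ties) or Kruskal–Wallis followed by Dunn's tie-corrected pairwise z
tests with Benjamini–Hochberg. Trend tests are Cochran–Armitage with equally
spaced scores for binary outcomes and a seeded permutation
Jonckheere–Terpstra (10,000 permutations, two-sided around the permutation
mean) for continuous ones. The deletion metric counts DEL records with
10 kb ≤ size ≤ 1 Mb, bounds inclusive, optionally intersected with a
common-fragile-site interval set.

## Ordinal treatment response

The proportional-odds model P(Y ≤ k│x) = logistic(θ_k − x·β) codes
PD = 0 < SD = 1 < PR = 2, so positive β means better response. Fitting is
Newton with analytic gradient and Hessian, step-halving, convergence at
gradient norm < 1e-8 within 100 iterations; Wald standard errors and p-values
come from the inverse observed information. Fits with |β| > 30 are flagged as
separated and excluded from screening. The univariate screen requires, for
binary features, at least 5 carriers in every observed response group
(continuous features are always eligible) and selects at p < 0.05, strict.

The ordered LASSO minimizes −loglik/n + λΣ|β| (cut points unpenalized) by
proximal gradient with backtracking line search; the backtracking
majorization makes the penalized objective non-increasing, which is asserted
at every step. Continuous features are standardized internally and
coefficients mapped back to the original scale; 0/1 features are left as-is.
λ is chosen by 5-fold stratified cross-validated deviance on a descending
warm-started grid (default 12 points, geometric from 0.5 to 1e-3); folds are
seeded. At λ = 0 the fit agrees with the Newton maximum-likelihood fit to
<1e-4 per coefficient, and for λ large all β shrink exactly to zero, leaving
the intercept-only cut points.

## Synthetic cohorts: what they emulate, and what they do not

The generator reproduces the statistical structure that the analyses consume.
Chromosomes are sequence-free coordinate spaces; each simulated SNV stores
the reference-strand trinucleotide implied by its sampled channel (on a
random strand, so the pyrimidine collapse is exercised), which avoids
simulating gigabases of sequence. Per-sample small-variant counts are
Poisson(TMB × genome Mb), split SNV:MNV:indel = 0.90:0.02:0.08; SNV channels
are multinomial draws from the sample's signature mixture over a synthetic
sparse-Dirichlet reference (clearly labeled SYN1..k — a stand-in, not a
curated catalog); positions are uniform. SV sizes are log-normal per type
with the deletion mode at log₁₀ size ≈ 5.1 (~128 kb). Kataegis injection
places ≥2 SNVs with ±20%-jittered gaps; noncoding-driver planting raises a
gene's expected cohort rate to multiplier × its local nonannotated rate by
adding Poisson((m−1)·rate·size) events over a chosen fraction of samples; MSI
injection adds 1-bp indels inside mononucleotide stretches of chosen target
genes at multiplier × the catalog's background indel rate (the default
multiplier, 3000, reflects that slippage at mononucleotide runs in
mismatch-repair-deficient tumors runs orders of magnitude above the ~5e-7/bp
background). Response labels are drawn from the exact cumulative-logit model,
so parameter recovery is well-posed. One master seed fans out deterministically
to per-stage child seeds, all logged in the truth object and run manifest.

Defaults mirror the cohort the package targets where a published value
exists: mean TMB 7/Mb, ~3% MSI samples, ~24% of samples with an injected
focus, noncoding genes of 3–9 kb. The genome defaults (2 × 40 Mb chromosomes,
15 noncoding genes, 200 nonannotated regions with at least 10 within ±1 Mb of
every noncoding gene) are scaled down from a real genome but keep the
local-baseline test well-posed: an exact signed-rank over b baselines cannot
fall below 2⁻ᵇ, so b ≥ 10 is needed for a single gene to survive Hochberg
across ~15 tests — consistent with the density of intergenic sequence around
real genes. Problem sizes in the test and acceptance suites (cohorts of 200
samples, 100–200 replicate seeds) were chosen so each suite completes in
minutes on one CPU.

What the generator does **not** emulate: real trinucleotide abundances and
regional mutation-rate covariates (replication timing, chromatin), germline
variation, purity/ploidy and subclonality, selection on coding sequence,
linked SV/CNV structure, and treatment-specific signature profiles. Passing
the recovery suites therefore demonstrates that the procedures detect what
they claim to detect under their own assumptions — not that those assumptions
hold in real tumors; in particular the noncoding scan's null calibration
fails even under these idealized conditions (see above), which real-data
covariates would only worsen.

## Embedded published counts

`mcrc.datasets` carries the printed mutation-frequency contingency tables
comparing the 429-sample metastatic WGS cohort with primary CRC (TCGA-DFCI,
n = 1949; ICGC, n = 866 for noncoding genes) and with an independent
targeted-sequencing metastatic cohort (Yaeger et al., n = 321), together with
the published p-values. The package recomputes the Fisher and Hochberg
statistics from the counts; recomputing adjusted values from the *printed*
(rounded) p-values reproduces the published adjusted values at the top ranks,
which is the comparison the acceptance script reports.
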