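# mcrc

Somatic-landscape analysis for metastatic colorectal cancer (mCRC)
whole-genome-sequencing cohorts.

Cohort studies of metastatic CRC ask a recurring set of questions of their
somatic variant catalogs: which mutational processes (COSMIC-style SBS/DBS
signatures) shaped each tumor and how do prior treatments change them; where
are kataegis foci of clustered hypermutation; which noncoding genes are
mutated above their local background rate; which genes are preferentially hit
in microsatellite-instable (MSI) tumors beyond what their microsatellite
content predicts; how do mutation frequencies compare with primary-CRC
cohorts; and which genomic features associate with ordinal treatment response
(PD < SD < PR). This package implements that analysis chain as a tested
library with a thin CLI, for computational biologists who have variant-level
calls (the patient-level data of such studies are typically restricted-access)
or who want to study the statistical behavior of these procedures on
synthetic cohorts with planted ground truth.

## Methods at a glance

- **Signature refitting** — per sample, solve the non-negative least-squares
  problem min‖R·e − c‖₂, e ≥ 0, where R is the 96-channel (or 78-channel
  doublet) reference profile matrix and c the sample's context counts;
  relative contributions are e/Σe. Dominant signatures are those with ≥10%
  contribution in ≥10 samples; samples are clustered on median-centered
  contributions (1 − Pearson, average linkage).
- **Kataegis** — per chromosome, segment log₁₀ intermutation distances by the
  exact dynamic-programming minimizer of Σ segment SSE + γ·(#segments); call a
  segment with ≥5 SNVs and mean IMD ≤ 2 kb.
- **Noncoding driver scan** — per recurrent noncoding gene (≥5% of samples
  mutated), one-sided Wilcoxon signed-rank of the mutation rates
  (events/bp) of nonannotated regions (>1 kb) within ±1 Mb against the gene's
  rate, Hochberg step-up across genes.
- **MSI enrichment** — count mononucleotide stretches of length 6–13 in exon
  sequences; per high-burden-associated gene, a one-sided sign test of its
  MSI-sample mutation frequency against control genes with a comparable
  (±10%) number of MSI-prone sequences; cluster association is tested by
  Fisher exact plus a permutation test that redraws mutated samples with
  probability ∝ TMB.
- **Cohort statistics** — two-sided Fisher exact tests (point-probability
  rule) with Hochberg adjustment, Mann–Whitney / Kruskal–Wallis + Dunn,
  Cochran–Armitage and Jonckheere–Terpstra trend tests, TMB
  (SNV+MNV+indel per Mb, high if >10), and 10 kb–1 Mb deletion counts.
- **Treatment response** — proportional-odds model
  P(Y ≤ k│x) = logistic(θ_k − x·β), fitted by Newton iterations; a univariate
  screen (binary features need ≥5 events per response group, select at
  p < 0.05) followed by an L1-penalized cumulative-logit fit (ordered LASSO,
  proximal gradient, penalty chosen by 5-fold cross-validated deviance).
- **Synthetic cohorts** — `mcrc.synthetic` generates genomes, signature-mixed
  catalogs, kataegis foci, planted noncoding drivers, MSI indel excess and
  proportional-odds outcomes, all seeded and with the planted truth recorded.

## Worked example

```python
from mcrc.stats import fisher_2x2, hochberg_adjust
from mcrc import datasets

res = fisher_2x2(317, 112, 1123, 826)   # TP53: 317/429 mCRC vs 1123/1949 primary
print(f"TP53  OR={res.odds_ratio:.2f}  p={res.p_two_sided:.3g}")
table = datasets.driver_gene_table()
adj = hochberg_adjust(table.printed_p.to_numpy())
print(f"TP53 Hochberg-adjusted p = {dict(zip(table.index, adj))['TP53']:.2g}")
```

```
TP53  OR=2.08  p=2.04e-10
TP53 Hochberg-adjusted p = 4.7e-09
```

TP53 mutations are about twice as likely in the metastatic cohort as in
primary CRC, and the enrichment survives correction across the 23 driver
genes. On a synthetic cohort:

```python
from mcrc import synthetic as syn, kataegis, signatures

genome = syn.build_genome(seed=0)
ref = syn.synthetic_signature_reference(5, seed=0)
expo = syn.random_exposures(["S000", "S001"], ref.signatures, seed=0)
truth = syn.SimulationTruth(exposures=expo)
cat = syn.simulate_catalog(genome, truth, ref, mean_tmb=7.0, seed=0)
cat, focus = syn.inject_kataegis(cat, genome, "S000", "chr1", 8, 500, seed=1)
print(kataegis.detect_kataegis(cat)[0].to_string(index=False))
print(signatures.compute_tmb(cat, genome.total_mb).round(2).to_string())
```

```
sample_id chrom    start      end  n_snvs   mean_imd
     S000  chr1 10278750 10282374       8 517.714286
           n_mutations   tmb  high_tmb
sample_id
S000               577  7.21     False
S001               581  7.26     False
```

The injected 8-SNV focus (gaps ≈500 bp) is recovered exactly; both samples sit
near the requested burden of 7 mutations/Mb and below the high-TMB cutoff.

The full chain runs from one configuration:

```bash
mcrc run --seed 11 --out runs/demo        # simulate → signatures → kataegis →
                                          # noncoding-scan → msi-scan → stats → response
mcrc kataegis --variants runs/demo/variants.tsv --gamma 1.0
```

Each run writes per-stage TSV tables plus `manifest.json` recording seeds,
thresholds and output checksums; reruns with the same seed are byte-identical.

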