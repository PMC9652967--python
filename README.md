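# brcaness

Transcriptomic scoring of **BRCAness** — the homologous-recombination-deficiency
(HRD) phenotype that mimics germline *BRCA1/2* mutation — in bulk breast-cancer
expression cohorts, for computational biologists who want the full chain from
signature discovery to clinical association as reusable, testable code.

The package implements:

- **Signature discovery.** For every gene, the ROC-AUC separating
  *BRCA1*-mutant from wildtype samples by expression is computed with midrank
  tie handling (AUC = U/(n₁n₀)); the signature is the set of genes with
  AUC > 0.650 in *every* cohort screened. Each cohort is screened on its native
  scale — AUC is rank-based, so no cross-cohort normalization is needed.
- **Single-sample gene-set scoring** (GSVA-style, from scratch). Each gene's
  expression is replaced by a kernel-CDF estimate across samples
  (Gaussian kernel, bandwidth *h* = s/4, or the empirical CDF); within each
  sample, genes at 1-based rank *r* of *p* get the symmetric weight |p/2 − r|;
  a weighted Kolmogorov–Smirnov walk down the ranking yields an enrichment
  score in [−1, 1] per (gene set, sample). The BRCAness score is this statistic
  for the signature; the DNA-repair score uses the 150-gene Hallmark DNA repair
  set.
- **Immune scores.** CYT = √((PRF1 + 0.01)(GZMA + 0.01)) on TPM, and an
  immune-checkpoint index (ICI): mean z-scored log2 expression over a
  configurable checkpoint panel.
- **Stratified association statistics.** Top-tertile stratification
  (high = score strictly above the 2/3 empirical quantile, per cohort), then
  Mann-Whitney U, Kruskal-Wallis, Fisher exact, Spearman, ROC-AUC for outcome
  prediction, and Kaplan-Meier/log-rank.
- **A synthetic two-cohort study generator** with planted signal: ~5% mutation
  prevalence, 40 planted signature genes mean-shifted by 2 within-gene SDs in
  mutants (per-gene AUC ≈ Φ(2/√2) ≈ 0.921), per-gene lognormal noise, a cohort
  scale factor, and a response label logistically linked to the true signal —
  with the ground truth returned for recovery testing.

## Worked example

Simulate a two-cohort study, discover the signature, then score and associate
one cohort:

```
$ brcaness simulate --preset two-cohort --seed 7 --n-samples 200 --n-genes 600 --out-dir sim
wrote cohort cohortA: 600 genes x 200 samples
wrote cohort cohortB: 600 genes x 200 samples

$ brcaness discover --expr sim/expr_cohortA.tsv --clin sim/clin_cohortA.tsv \
    --expr sim/expr_cohortB.tsv --clin sim/clin_cohortB.tsv --out signature.gmt
signature: 43 genes -> signature.gmt

$ brcaness associate --expr sim/expr_cohortA.tsv --clin sim/clin_cohortA.tsv \
    --signature signature.gmt --with-cyt --with-ici --out-dir assoc
22 association rows -> assoc/associations.tsv
```

The screen found 43 genes exceeding AUC 0.650 in both cohorts; against this
study's 40 planted genes that is precision 0.93, recall 1.00. The first
association rows:

```
cohort  score          covariate  test          statistic  p_value          n
cohort  brcaness       mutation   mann_whitney  2256       6.625366258e-09  200
cohort  brcaness       mutation   roc_auc       1                           200
cohort  brcaness_high  mutation   fisher_exact  inf        9.818701787e-07  200
```

The BRCAness score separates mutant from wildtype samples perfectly here
(ROC-AUC 1.0 — the signature was discovered on exactly this planted effect),
and the high-BRCAness tertile is significantly enriched for mutants
(Fisher p ≈ 1e-6; the odds ratio is infinite because no mutant fell in the
low group). `brcaness run --preset synthetic --seed 17 --out-dir out` chains
all steps, and `brcaness run --config pipeline.yaml` drives real cohorts; both
are byte-deterministic given the seed/config.

Two GMT fixtures ship with the package: `hallmark_dna_repair.gmt` (150 genes)
and `brcaness_34_synthetic.gmt`, a synthetic stand-in 34-gene BRCAness panel
for demonstrations — real analyses should use a signature discovered from
their own cohorts (see `docs/methods.md`).

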