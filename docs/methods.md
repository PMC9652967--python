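# Methods

## Scope and model

The package scores the BRCAness phenotype — homologous-recombination
deficiency (HRD) that phenocopies germline *BRCA1/2* loss — from bulk
expression alone. The underlying model is deliberately simple: genes whose
expression discriminates *BRCA1*-mutant from wildtype tumors consistently
across independent cohorts form a signature, and a single-sample enrichment
statistic of that signature is the BRCAness score. Everything downstream
(tertile groups, association tests, response ROC) treats that score as an
ordinary per-sample covariate.

## Signature discovery

Per gene, the ROC-AUC between mutant and wildtype expression is computed via
the rank-sum identity AUC = (R₁ − n₁(n₁+1)/2)/(n₁n₀) with midranks, which
equals pair counting with half-credit for ties; a zero-variance gene is
exactly 0.5. The signature is the intersection of genes with AUC **strictly**
greater than the threshold (default 0.650) in every cohort, ordered by mean
AUC descending (ties by symbol). Design points:

- Only the over-expressed-in-mutant tail is kept by default; consistently
  under-expressed genes (AUC < 1 − threshold everywhere) can be admitted as
  sign-flipped members via `require_both_directions`, off by default because
  the screen's defining rule names only the upper tail.
- Screening is per cohort on the native scale. AUC is invariant to any
  monotone within-cohort transform, so array intensities and TPM cohorts can
  be screened side by side and only the gene lists intersected; no attempt is
  made to harmonize scales across cohorts.

## Single-sample scoring engine

The scoring statistic follows the gene-set variation analysis family:

1. *Kernel CDF.* Per gene i, zᵢⱼ = (1/n) Σₖ Φ((xᵢⱼ − xᵢₖ)/hᵢ), hᵢ = sᵢ/4
   (sample SD, ddof = 1), or the ECDF #{xᵢₖ ≤ xᵢⱼ}/n. The Gaussian kernel
   expects log2-scale input and drops zero-variance genes with a warning
   (they carry no ranking information; their removal provably leaves other
   genes' scores unchanged). The ECDF variant is fully rank-based and
   scale-free.
2. *Symmetric rank weights.* Within a sample, genes are ordered by z
   descending, ties broken by ascending gene index for bit-reproducibility;
   position r of p carries weight |p/2 − r|, emphasizing both extremes.
3. *Weighted KS walk.* ν(l) = Σ_{set, r≤l} w_r^τ / Σ_{set} w_r^τ −
   #{non-set, r≤l}/(p − m). `mx_diff` (default) returns
   max(ν,0)_max + min(ν,0)_min; `max_deviation` returns ν at the first
   position of maximal |ν|. Both lie in [−1, 1].

Defaults τ = 1, Gaussian kernel, `mx_diff` are the method family's standard
choices and are surfaced as `GsvaParams`. Scores are always computed within
one cohort — the kernel CDF is cohort-relative — matching the per-cohort
tertile convention. A degenerate corner exists by construction: a singleton
set whose gene sits exactly on the zero-weight middle rank (even p) has a
zero denominator and raises an error rather than returning an arbitrary
value. Sets retaining fewer than `min_set_genes_present` (default 5) matched
genes are errors, not silent small-set scores. Gene matching is
case-insensitive exact symbol match after whitespace stripping; no alias
resolution.

The test suite holds a second, loop-based implementation of the whole chain
(tests/oracles.py) and checks equality on randomized small instances to
1e-12 (ECDF) / 1e-9 (Gaussian).

## Composite scores

- **BRCAness / DNA-repair**: the engine applied to the discovered signature
  and to the 150-gene Hallmark DNA repair set respectively.
- **CYT** = √((PRF1 + 0.01)(GZMA + 0.01)) on TPM — geometric mean of the two
  cytolytic effector genes with a small pseudo-expression so all-zero samples
  stay defined (offset in TPM units, configurable).
- **ICI**: mean over a checkpoint panel (default PDCD1, CD274, CTLA4, LAG3,
  HAVCR2, IDO1, PDCD1LG2, TIGIT) of per-gene z-scored log2 expression;
  zero-variance genes are dropped and fewer than two usable genes is an
  error. The panel and the aggregation are this package's documented
  convention for "overall checkpoint expression" — no published formula is
  being claimed.

## Packaged gene-set fixtures

`hallmark_dna_repair.gmt` carries the 150-gene Hallmark DNA repair panel as
distributed by MSigDB, transcribed for offline use; a few memberships may
deviate from the canonical release, so installations that have MSigDB access
should prefer the upstream file. `brcaness_34_synthetic.gmt` is a **synthetic
stand-in**: a 34-gene panel of well-known BRCA1-mutation-associated
DNA-repair and proliferation genes with the size and character of a
discovered BRCAness signature, shipped so examples and demos run without any
download. It is not a published signature; real analyses should score a
signature discovered from their own cohorts.

## Stratification and statistics

The high group is score > empirical quantile at 1 − high_fraction (default
top tertile), quantile by linear interpolation between order statistics; ties
at the cutoff fall low, and stratification is per cohort on all scored
samples. Group tests are the standard nonparametrics (Mann-Whitney U —
exact for small untied samples, tie-corrected normal approximation otherwise;
tie-corrected Kruskal-Wallis with χ² p; two-sided Fisher exact by
hypergeometric probability-mass summation, p = 1 by convention on a zero
margin; Spearman with midranks; two-group log-rank with Kaplan-Meier
product-limit curves). p-values are reported raw with no multiple-testing
correction, mirroring per-test α = 0.05 reporting. U/(n₁n₂) equals the
package's AUC on pooled data by construction, and the returned ROC staircase
integrates (trapezoid) exactly to the midrank AUC.

## Synthetic studies

Per gene g and sample j, log2 expression is
N(μ_g + δ·σ_g·[mutant]·[planted], σ_g) with μ_g ~ N(5, 2), σ_g ~ U(0.5, 1.5);
matrices are exported as TPM via 2^x − 1 (clipped at 0), so the TPM → log2
path is exercised end to end. Defaults are the reference condition used
throughout the tests: 500 samples/cohort, 2000 genes, 40 planted, prevalence
0.05 (roughly double the TCGA *BRCA1* rate, keeping ≈25 mutants per cohort
for stable screens), δ = 2.0 (per-gene AUC ≈ Φ(2/√2) ≈ 0.921). Response
labels are Bernoulli(logistic(−1.1 + 1.0·true_signal)) — ≈25% baseline
response rising with the mean planted-gene z-deviation. A cohort scale
factor multiplies TPM and verifiably changes no rank-based result. The
optional `embed_real_symbols` flag renames a block of *background* genes to
real symbols (the DNA-repair panel, the checkpoint panel, PRF1/GZMA) so the
named-gene scores run on synthetic data; planted genes never come from that
block.

Not emulated: platform/batch artifacts, gene-gene correlation beyond the
shared mutation effect, zero inflation, copy-number signal. Passing recovery
tests therefore demonstrates correctness of the machinery under the stated
generative model, not performance on real cohorts; the original study's
cohort-level numbers (e.g. score-vs-mutation AUC ≈ 0.71-0.74 on thousands of
patients) depend on data this package deliberately does not download.

## Problem sizes and numerical choices

Module tests run on reduced instances (hundreds of samples, hundreds of
genes, 3-5 seeds) chosen as the smallest sizes at which the tested signal is
unambiguous; the two headline recovery properties (dual-cohort screen
precision/recall ≥ 0.9, high-tertile mutant enrichment by Fisher) run at the
full reference condition over 10 seeds. The Gaussian kernel transform is
chunked over genes to bound the n×n pairwise buffer at cohort scale. All
tie-breaks are deterministic; reruns of the pipeline with a fixed seed/config
produce byte-identical outputs (timestamps appear only in logs). Duplicate
gene rows on input collapse to the row with the highest mean (the usual
many-probes-per-gene convention); missing expression values are rejected
rather than imputed because the rank machinery assumes complete rows.

## Known limitations

- The shipped 34-gene panel is a stand-in (above); results obtained with it
  characterize the pipeline, not the published signature.
- ICI is a reconstruction with a configurable panel, not a validated index.
- The screen has no expression-level floor and no FDR control — it reproduces
  a plain threshold rule; stability beyond multi-seed recovery is out of
  scope.
- Immune-cell deconvolution fractions, HRD and related mutation-derived
  scores are accepted as precomputed clinical columns only.
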