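# Methods

This note documents the models, defaults and design choices behind
`modscreen`, in the spirit of a statistical-methods appendix.

## The screen being modeled

A modifier screen crosses a sensitized strain (one expressing a
transgene that produces a quantitative, degenerate phenotype — here,
reduced adult eye area in pixels) to every strain of an inbred reference
panel. F1 progeny share half their genome with the donor and half with
the panel strain, so variation in the readout across panel backgrounds
measures the dominant effect of natural variation on the sensitized
process. The analysis stages are: per-strain summaries and a background
ANOVA; mixed-model GWAS of strain means; variant-to-gene assignment;
variant-level gene set enrichment; and many-to-one validation tests of
candidate knockdowns.

## Mixed-model association

Per variant, on the n strain means y:

    y = α + xβ + u + ε,  u ~ MVN_n(0, λ τ⁻¹ K),  ε ~ MVN_n(0, τ⁻¹ I_n)

* K is the centered marker-based relatedness matrix
  K = (1/p) Σ_k (x_k − x̄_k 1)(x_k − x̄_k 1)ᵀ. Missing calls are imputed
  to the variant mean before centering (a mean-imputed call contributes
  zero), so monomorphic variants contribute nothing and n stays constant
  across variants.
* Fitting: K is eigendecomposed once per scan and cached. For a
  candidate λ the model is rotated into the eigenbasis, each coordinate
  weighted by 1/(λ dᵢ + 1), and (α, β) solved by weighted least squares.
  λ is maximized via a 21-point grid on log₁₀λ ∈ [−5, 5] followed by
  bounded Brent refinement (xatol 1e−6). The genome scan estimates λ
  under REML, matching the convention of the standard mixed-model GWAS
  tools for Wald tests; plain ML is available behind a flag. The choice
  matters: per-variant ML λ̂ is biased toward the bracket boundary when
  (λ, τ) are weakly identified and measurably inflates the null type-I
  rate (≈ 0.065 vs ≈ 0.056 for REML at p < 0.05 on 200-line panels).
* Testing: Wald p from (β̂/se)² against χ²₁. The se uses the unbiased
  residual-variance divisor n − c (c = 2 regression coefficients); with
  λ pinned at 0 the fit reduces exactly to OLS with its textbook se. No
  small-sample t/F correction is applied beyond that divisor; on
  200-line panels the measured null type-I error at p < 0.05 is ≈ 0.054
  (see the acceptance script), the expected mild χ² vs t gap at this n.
* Variant filters precede the scan: biallelic sites only, missingness
  ≤ 0.20, sample MAF ≥ 0.05 (boundary inclusive). Candidate variants
  use the screen's conventional cutoff p < 10⁻⁴, strict.
* λ_GC = median(χ²₁ quantiles of observed p) / 0.4549 diagnoses residual
  stratification; values near 1 on null simulations confirm the GRM
  absorbs the panel's block structure.

## Variant-to-gene assignment

A variant belongs to a gene if it lies in the gene body or within 1 kb
of it, inclusive at exactly 1000 bp. Categories: UTR (UTRs are exonic
subregions and take precedence over plain exon for the same base), exon,
intron, upstream/downstream by strand. Across genes the category
priority is exon > UTR > intron > flank (upstream and downstream share
one tier); ties at equal priority go to the nearer gene, then
lexicographic gene id, making assignment independent of input order.

## Gene set enrichment

Gene score = −log₁₀ of the minimum variant p among the gene's assigned
variants. Minimum-p is the simplest statistic consistent with
single-variant candidate genes; it is deliberately configurable in
spirit (alternatives such as Fisher combination would over-reward long
genes with many variants unless length-corrected). Genes are ranked
descending, ties broken lexicographically.

The enrichment score is a weighted KS running sum: hits add
|score|^w / Σ_hits |score|^w (w = 1 by default), misses subtract
1/(N − N_H); ES is the maximum signed deviation. At w = 0 the statistic
reduces to the classical two-sample KS statistic on ranks, which the
tests exploit as an oracle.

Significance uses gene-label permutation: each permutation draws N_H
positions without replacement and recomputes ES with the same score
profile. Phenotype-level permutation is not possible here because only
summary statistics reach this stage; the gene-label null is the declared
substitute. p_nominal = (1 + #{ES_perm ≥ ES_obs})/(1 + n_perm)
(mirrored for negative ES) — the add-one convention keeps p > 0. NES
divides ES by the mean same-sign permuted |ES|. Correction across sets
is Benjamini–Hochberg. Reported sets must pass, strictly: ES > 0,
more than 3 member genes present, corrected p < 0.05.

With n_perm = 1000 and ~50 sets, the smallest achievable corrected p is
≈ 0.05, so a set passes the p_adj filter only when it is the clear
leader of the family; raise `n_perm` for finer resolution.

## Dunnett validation statistics

Knockdown groups are compared to their genetically matched control with
pooled-variance many-to-one t statistics. The family-wise adjusted
two-sided p is P(max_j |T_j| ≥ |t_obs|) under the joint null in which
the T_j are correlated through the shared control mean and the shared
variance estimate (correlation √(n_j n_k / ((n_j+n_0)(n_k+n_0))) for
unbalanced groups). The tail is evaluated by seeded Monte Carlo
(default 200 000 draws, standard error ≈ 5 × 10⁻⁴) rather than
closed-form tables, which only cover balanced designs. Two-sided
throughout, since screens report both enhancers (smaller eye) and
suppressors (larger eye). The two control genotypes of a typical RNAi
library (attP40/attP2) are never pooled; the caller picks the matched
control.

## The synthetic panel generator

The generator emulates the features of an inbred reference panel that
matter to the statistics:

* **Genotypes** are homozygous (coded 0/2; heterozygotes never occur,
  matching fully inbred lines), at variants with allele frequency drawn
  uniformly from [0.05, 0.5]. Relatedness is block-structured: lines are
  assigned round-robin to `n_blocks` (default 20) blocks; per variant a
  block inherits an ancestral allele and each line copies it or redraws
  with probability `block_mutation_rate` (default 0.5). This is the
  simplest structure that makes K informative.
* **Phenotypes**: line genetic value g = Σ xβ + u with
  u ~ MVN(0, λτ⁻¹ K̃), where K̃ is the realized GRM rescaled to unit mean
  diagonal so λτ⁻¹ is the average polygenic variance per line.
  Individual observations are baseline + g + N(0, replicate_sd²), with
  10–15 replicates per strain. Defaults: baseline 14 000 px (inside the
  observed strain range of real screens), λ = 1, τ⁻¹ = 10⁶ px²
  (polygenic SD ≈ 1000 px, giving a strain range of several thousand
  px), replicate SD 400 px (within-strain variation far below
  between-strain variation, as observed). Within-strain replicate
  variance is not published for the real screens; hundreds of px is the
  right order of magnitude given printed per-strain SDs.
* **Causal variants** (default 8, |β| = 800 px per allele with random
  sign) are placed inside ±1 kb of distinct genes of one planted gene
  set, so the GWAS → assignment → GSEA chain can in principle recover
  the set. 800 px is modest relative to the 1350–2800 px shifts that
  validated single-gene knockdowns produce.
* **Annotation**: ~300 genes with 1.5–8 kb spans, 1–4 exons, optional
  UTRs, on a 3 Mb chromosome; always includes two genes < 2 kb apart
  and a ≥ 2 kb gene desert as assignment edge cases. **Gene sets**:
  50 sets of 4–30 genes sampled without replacement from the gene list;
  the planted set has 10 genes.
* All draws come from one `numpy.random.Generator` seeded from the
  config; identical configs are bit-identical.

What the generator does **not** emulate: realistic linkage
disequilibrium decay, inversions, allele-frequency spectra, infection
status covariates, non-normal phenotype noise, or shared variants
between gene sets' biology. Passing tests therefore demonstrate the
statistical machinery is correct and calibrated under the stated model,
not that any real screen's biological findings are reproduced.

## Problem sizes used in tests and the acceptance script

Calibration checks run at the scale where their expectations are sharp
but the suite stays quick: null type-I error on three 200 × 2000 panels
(6000 tests), λ recovery over 50 panels of 500 variants, GSEA p
calibration on 500 random sets with 999 permutations, Dunnett
family-wise error on 2000 (suite) / 500 (script) null families, and
end-to-end planted-set recovery over 20 (suite) / 8 (script) seeds of
the default 200 × 5000 screen.

## Known limitations

* Single-chromosome simulation; no leave-one-chromosome-out GRM, so a
  tested variant also contributes (1/p of) its own signal to K — at
  p ≥ 500 variants the effect is negligible.
* λ is re-optimized per variant (the exact but slower convention);
  no approximation reuses the null-model λ.
* The gene-level min-p score ignores gene length/variant count; long
  genes get more chances at a small p, which the gene-label permutation
  null only partially absorbs.
* No covariates in the LMM (sex is handled by filtering to females
  upstream), no multi-variant models, no variant-level multiple-testing
  correction (candidates are nominations for functional validation, not
  confirmed associations).
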