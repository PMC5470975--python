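# Methods

This note documents the statistical procedures implemented in `lncprog`,
the design of the synthetic-data generator, the defaults and why they were
chosen, and the known limitations of both.

## Analysis model

The pipeline assumes a gene × sample matrix of log2 expression values that
has already been normalised and summarised to genes (probe re-annotation
and RMA-style normalisation are upstream concerns and out of scope). Sample
annotations distinguish five normal B-cell differentiation stages from a
tumor group, and tumor patients carry subtype (GCB / non-GCB), survival
(time in months, event indicator, OS or PFS endpoint) and clinical
covariates (gender, age, IPI 0–5).

### Differential screen

For each normal stage the tumor group is contrasted by a two-sample
*t* test. The default is the pooled-variance (Student) test with
df = nA + nB − 2; Welch is available. Values are log2, so the fold-change
filter |log2 FC| > log2(2) = 1 is a strict inequality, as is the *p*
threshold. Per contrast, *p*-values are Benjamini–Hochberg adjusted and the
significance call uses adjusted *p* < 0.05 by default; a raw-*p* switch
reproduces the alternative reading of the same workflow. Zero-variance
genes with equal means are assigned t = 0, p = 1 rather than NaN so that
downstream set logic stays total. The candidate set is the intersection of
per-stage significant genes; direction (up/down in tumor) must be read from
the per-contrast signs and is reported as "mixed" when inconsistent. A
one-way ANOVA *F* test across all six groups is attached to the candidates,
with Bonferroni correction whose family is the candidate set passed into
the call — the natural family when the ANOVA is used as a confirmation step
on a short list.

Moderated (empirical-Bayes) statistics are deliberately not implemented:
the screen specifies the ordinary *t* test, and moderation would change no
interface.

### Survival evaluation

* **Mean split.** The threshold is the arithmetic mean of the biomarker
  across the evaluated patients; values strictly below go to "low", values
  at or above to "high" (the boundary convention matters for reproducing
  mean-cutoff stratifications). A constant marker raises an explicit
  degenerate-split error rather than producing an empty stratum.
* **Kaplan–Meier.** Product-limit estimation is delegated to lifelines;
  curves are exported with at-risk counts, event counts and censor marks.
  Five-year rates are the right-continuous step value at t = 60 months.
* **Log-rank.** The standard observed-minus-expected statistic
  (lifelines), df = groups − 1. Under a two-group null with 50+50 subjects
  and no censoring its empirical size is ≈ 0.052 — slightly anticonservative
  but within the nominal band.
* **Cox proportional hazards.** Implemented in-package: Newton–Raphson on
  the partial likelihood, Efron tie handling by default (less biased with
  ties) with Breslow available, convergence at gradient ∞-norm < 1e-8 with
  step halving, covariates centred for numerical stability. Inference is
  Wald-based (HR = e^β, 95% CI, two-sided *p*), matching the reporting
  granularity of typical clinical tables. Constant covariates are reported
  as coef 0 / HR 1 / p 1 (no information). A coefficient escaping ±15 is
  treated as monotone partial likelihood (complete separation): the fit is
  capped, flagged `diverged`, and a warning is emitted. The implementation
  is verified against brute-force maximisation of the written-out partial
  likelihood on small instances and against lifelines on untied data.
  The dichotomised-marker model codes low = 1, so HR > 1 reads "low
  expression carries higher risk".
* **ROC/AUC.** AUC is the Mann–Whitney probability with ties counted 0.5;
  the default outcome is the event indicator at last follow-up. Because the
  choice of ROC endpoint (final status vs status at 60 months) is genuinely
  ambiguous in this kind of analysis, a flag switches to 5-year status with
  early-censored patients excluded.
* **Chi-square.** Pearson chi-square without continuity correction on 2×K
  count tables (clinicopathological association tables).
* **IPI stratification.** Patients are partitioned into IPI 0–2 and 3–5 and
  the mean-split comparison is repeated per stratum. The split threshold is
  the whole-cohort mean reused within strata (the cohort is classified
  once, then stratified); a per-stratum-mean option exists. Strata whose
  split leaves fewer than 2 patients in a group are skipped with a warning.

### Co-expression network

All unordered gene pairs among the supplied genes are tested.
Pearson correlation is the default (Spearman = Pearson on average ranks is
selectable globally). Significance uses Fisher's asymptotic test:
z = atanh(r), se = 1/√(n−3), two-sided p = 2·Φ(−|z|·√(n−3)); |r| = 1
returns an exact zero. The Bonferroni denominator is the number of pairs
actually tested in the run (zero-variance genes are excluded with a logged
count) — the most conservative defensible family. Edges are kept at
adjusted p < 0.01 by default; applying the threshold to raw p instead is a
documented switch, since the procedure being emulated can be read either
way. Edges are stored unweighted for topology but retain r, n and both
p-values for export (edge-list TSV with gene_a < gene_b, or GraphML).
The all-pairs computation is blocked over rows of the correlation matrix so
memory stays bounded for ~5,000-gene inputs; results are identical for any
block size. The pipeline default builds the network from the tumor samples
only (tumor co-expression programs are what the module analysis targets); a
switch uses all samples.

### Function prediction

* **MCL.** Canonical Markov clustering on the unweighted adjacency with
  self-loops: column-normalise, then alternate expansion (matrix power 2)
  and inflation (entrywise power 2.0 with renormalisation), pruning entries
  below 1e-5, until the matrix is stable within 1e-8 (a |r|-weighted mode
  exists). Clusters are read off attractor rows; attractors appearing in
  each other's rows merge. A node attracted by several clusters is assigned
  deterministically to the largest, then to the lexicographically smallest
  module id; unattracted nodes become singletons. Inflation 2.0 / pruning
  1e-5 are the canonical defaults; determinism comes from sorted node order.
* **Hubs.** One subnetwork per lncRNA with ≥ 1 protein-coding direct
  neighbor; the neighbor set is exactly the coding adjacency.
* **Enrichment.** Upper-tail hypergeometric p = P(X ≥ k) with parameters
  (N background, K term size, n_q query). Only coding genes participate;
  module queries are filtered to their coding members. The background is
  the coding genes of the network (a whole-catalog background is a flag):
  the inference is "which functions distinguish this module/hub from the
  rest of the network". Terms with raw p < 0.01 are kept, with no
  multiplicity correction by default — fidelity to the emulated procedure —
  and BH available as an option. Each lncRNA's module-route and hub-route
  term lists are reported separately with their overlap, the usual
  agreement check for guilt-by-association annotation.

## Synthetic-data generator

The generator emulates the statistical structure of a bulk microarray
study of B-cell differentiation and lymphoma; defaults mirror the study
design the pipeline targets.

* **Layout.** Five normal stages × 5 samples plus 170 tumor patients;
  300 coding genes and 60 lncRNAs, of which three modules of 30 coding + 5
  lncRNA genes carry planted co-expression.
* **Expression model.** Cell value = gene baseline (N(7,1)) + group shifts
  + module factor + N(0, σ²) noise, σ = 0.5 (a realistic within-group sd on
  the log2 scale of expression arrays). Each module has one latent factor
  per tumor sample with loading λ = σ·√(ρ/(1−ρ)), giving the closed form
  within-module correlation λ²/(λ²+σ²) = ρ (default ρ = 0.8). Factors act
  in the tumor samples, where the network is built; the normal stages
  serve the differential screen.
* **Biomarker.** The first lncRNA of module 1 is the planted biomarker:
  down-shifted by Δ = 2 log2 units in tumor and lifted by δ = 0.5 in GCB
  tumor samples (70:100 GCB:non-GCB margin). Its factor loading is reduced
  to 0.4 so that its tumor variance stays near the noise scale — keeping
  the tumor-vs-stage contrast detectable at n = 5 per stage — while its
  within-tumor correlation with module members (≈ 0.5) still clears the
  Bonferroni edge threshold at the 170-sample cohort (r ≈ 0.39).
* **Trio.** Three coding genes of module 1 share the biomarker's full
  deviation (tumor shift, GCB lift, stochastic part) plus noise calibrated
  so their within-tumor correlation with the biomarker is 0.95 — coding
  partners that are themselves differentially expressed and
  subtype-associated, the validation pattern the pipeline's
  `correlate_candidates` step looks for.
* **Survival.** Event times are exponential with hazard λ0·HR^{I(low)},
  where low/high is the mean split of the biomarker in the tumor cohort,
  HR = 1.7, and λ0 = ln 2 / 78 months. The 78-month baseline median makes
  the high-stratum 5-year OS ≈ 59% (and low ≈ 40%), the magnitude regime
  the evaluation layer is meant to operate in. Censoring is an independent
  exponential whose rate is solved (Brent) so the expected censored
  fraction is 0.3. Exponential proportional hazards makes Cox recovery an
  exact oracle: the mean recovered HR over 200 replicate cohorts lands in
  [1.6, 1.8].
* **Terms.** One planted term per module (its coding members) plus 20
  size-matched decoy terms drawn uniformly from the coding genes.
* **Covariates.** IPI scores are drawn with P(0–2) ≈ 0.67, gender with a
  ≈ 56% male margin, age N(62, 12) clipped to [18, 95] — all independent of
  the biomarker, so stratified analyses test the marker's effect within
  strata rather than confounding.
* **Determinism.** Every output is a pure function of (config, seed); the
  survival/covariate stream uses a seed derived from the config seed so
  expression matrices are unchanged by survival-side options.

What the generator does **not** emulate: probe-level and batch effects,
RMA artifacts, heavy-tailed or gene-dependent noise, correlated censoring,
non-proportional hazards, hierarchical GO structure, and realistic gene
counts (hundreds, not tens of thousands). Passing tests therefore
demonstrate that the pipeline recovers the effects it is designed to
detect under its own model assumptions — not that those assumptions hold
in any particular real dataset.

## Numerical choices and degenerate inputs

* Strict inequalities at every threshold (|log2FC| > 1, p < 0.05,
  adjusted p < 0.01), and the at-or-above-mean → high split convention.
* p-values are never NaN: zero-variance genes, constant covariates and
  empty queries all have defined conventions (p = 1 where there is no
  evidence, explicit errors where the operation is meaningless).
* Cox: gradient tolerance 1e-8, max 100 iterations, step halving with a
  relative 1e-12 likelihood-noise guard, separation cap |β| ≤ 15.
* MCL: stability tolerance 1e-8, max 100 iterations, pruning 1e-5, columns
  emptied by pruning get their self-loop restored; deterministic module ids
  ordered by smallest member label.
* Missing expression values are rejected at load by default (row-mean
  imputation is an explicit flag) because silent imputation would distort
  correlation p-values downstream.

## Known limitations

* Fisher's asymptotic z-test is accurate at conventional levels (empirical
  size 0.05 ± 0.01 at n = 36) but anticonservative in the extreme tail at
  small n: at the Bonferroni-scale cutoffs used for edge selection
  (raw p ~ 5e-7 with ~2·10⁴ pairs and n = 36) the exact null tail of r is
  t-distributed and ≈ 5× heavier than the asymptotic formula claims, so the
  realised family-wise error of edge selection at n = 36 is ≈ 5%, not ≤ 1%.
  With larger sample counts (the 170-sample default) the discrepancy
  shrinks. The test is implemented exactly as specified; users screening
  very small cohorts should prefer the exact t reference for pair
  significance if strict FWER control matters.
* Cox inference is Wald-only; likelihood-ratio or score tests are not
  exposed, and separation is flagged rather than resolved (no Firth
  penalisation).
* The mean split is a convention, not an optimised cutpoint; no correction
  for cutpoint selection is needed or applied.
* Multivariate Cox tables depend on covariate coding; this package codes
  low-marker = 1, male = 1, GCB = 1, IPI 3–5 = 1, and reports coefficients
  under exactly that coding.
* MCL on overlapping attractor systems uses a deterministic but arbitrary
  tie-break (largest module, then smallest id); alternative tie-breaks give
  partitions differing on boundary nodes.
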