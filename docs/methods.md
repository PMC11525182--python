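# Methods

This note documents the models and procedures implemented in `setrvat`, the
assumptions behind them, the tunable parameters and their defaults, what the
synthetic cohorts do and do not emulate, and the numerical choices that matter
for reproducing results.

## The gene impairment model

The score of a gene for an individual is a set function of the annotation
vectors of the qualifying rare variants the individual carries in that gene:

ψ(V) = σ(ρ(max{φ(x) : x ∈ V})), with ψ(∅) := 0.

* **φ** — variant embedding, fully connected, two layers of width 20.
* **max** — element-wise maximum over the set dimension. This fixed pooling
  makes ψ exactly invariant to member order and duplication, and encodes the
  biological prior that one sufficiently damaging allele can impair a gene.
* **ρ** — read-out, two hidden layers of width 10, linear output.
* **σ** — logistic squashing; scores live in (0, 1).
* Activations are leaky rectifiers with negative slope 0.01.

The empty set is short-circuited to exactly 0 rather than fed through ρ: a
non-carrier has no measured impairment, and a constant offset ρ(0) would be
absorbed by the association test's intercept anyway, so 0 keeps exported
score matrices interpretable.

Variable-length sets are batched by padding to the batch maximum with entries
excluded from the max; the contract that padding can never change a score is
enforced by test.

**Training.** ψ is shared across variants, genes and traits; per-trait linear
heads carry covariate coefficients and one weight per seed gene. The loss is
the mean across traits of the per-trait MSE on quantile-transformed
phenotypes; data points are individual–phenotype pairs, shuffled each epoch.
Optimisation uses AdamW (learning rate 10⁻³, decoupled weight decay at the
optimizer default 0.01, batch size 1,024) for at least 50 and at most 1,000
epochs, returning the checkpoint with the lowest validation loss; validation
holds out 20% of individuals, drawn independently per trait. Early-stopping
patience is 10 epochs without improvement (a choice this package fixes; only
the epoch bounds are inherent to the method). Covariates are standardised to
zero mean and unit variance before training; annotation columns are likewise
standardised, and both transforms are stored in the checkpoint so a trained
module can score new cohorts consistently. ρ's output layer is linear before
the logistic (the natural reading of the architecture; nothing downstream is
sensitive to this choice). The network and the backward pass are written in
NumPy; gradient correctness is checked against central finite differences in
the test suite, and the whole training loop is deterministic given its seed.

**Cross-validated ensembling.** Individuals are partitioned into K near-equal
folds (default K=5); for each fold, R restarts (default R=6) are trained on
the other K−1 folds with restart seeds derived deterministically from
(base seed, fold, restart). A training-cohort individual is scored by the mean
of ψ over exactly the R models of its held-out fold; an external individual by
the mean over all K·R models. Model-set disjointness (no model that trained on
an individual ever scores that individual) is machine-checked, not assumed.
Seed-gene discovery runs once on the full cohort before the folds are formed,
mirroring the workflow this scheme comes from; the mild circularity this
implies is discussed under Limitations.

## Qualifying variants, tests and gating

* Variant-to-gene assignment: a variant belongs to a gene if it lies within
  300 bp of any exon (1-based closed coordinates; the boundary is inclusive).
  A variant near two genes counts for both.
* Qualifying variants: MAF strictly below 0.1% for association testing and 1%
  for training, CADD-PHRED strictly above 5.
* MAF enters the annotation vector as [p(1−p)]^(−1/2).
* Burden/SKAT seed discovery: all four combinations of {pLOF, missense} masks
  with {burden, SKAT}, Beta(MAF; 1, 25) variant weights. Burden is the
  weighted dosage sum; its score test is
  T = (g̃ᵀr)² / (σ̂² g̃ᵀg̃) ~ χ²₁ with g̃ the burden residualised on the
  covariates. SKAT uses Q = rᵀGW²Gᵀr with eigenvalue weights from
  σ̂²·(WGᵀMGW). Markers with minor allele count ≤ 10 are collapsed for SKAT
  into a pseudo-marker holding each individual's maximum allele count across
  the collapsed set (weighted at the pseudo-marker's own empirical frequency);
  genes with more than 5,000 markers are skipped.
* Per-gene combination: Bonferroni, min(1, m·min p) with m the number of
  tests that produced a p value (a skipped test protected nothing). Gene-level
  correction: Bonferroni across the genes tested for that trait, i.e. those
  passing the EAF gate.
* EAF gate: a gene is testable when CAF × n ≥ 50, where CAF sums qualifying
  MAFs and n is the cohort size (quantitative) or case count (binary).
* Binary traits: a logistic-null score test (working residuals,
  expected-information variance) is provided for both discovery and
  association, but is flagged — at low case counts with strong rare effects it
  is not reliably calibrated. The robust route for binary traits is
  pseudodosage export to an external Firth-penalised tester.
* Conditional analysis appends caller-supplied common-variant dosages to the
  covariates and re-runs the score test; columns collinear with the existing
  design are dropped with a warning. Selecting the conditioning variants
  (clumping, windowing) is the caller's responsibility.

**Chi-square-mixture tail.** SKAT's null is a positively weighted mixture of
χ²₁ variables. Imhof's inversion integral is evaluated adaptively and trusted
while its quadrature error is below 2% of the value and p > 10⁻⁴; beyond that
the oscillatory integral cancels catastrophically, so Kuonen's saddlepoint
(Lugannani–Rice) approximation takes over, which keeps a few-percent relative
accuracy arbitrarily deep in the tail. A four-moment (Liu-type) approximation
is retained as an internal cross-check; it deviates by up to ~0.02 absolute in
the bulk, which is why it is not the primary method. The implementation is
validated against large Monte-Carlo samples and against permutation oracles
of the full tests.

## Synthetic cohorts

The generator produces the statistical structure the method assumes, with the
impairment function known exactly:

* **Genotypes** — independent Binomial(2, MAF) draws per individual, stored
  sparsely; MAFs log-uniform on (10⁻⁴, 10⁻²), matching the heavy rare tail of
  site-frequency spectra without modelling demography. Default 100 variants
  per gene, so that the qualifying CAF of a typical gene gives EAF ≈ 50–60 at
  cohorts of 3,000–4,000 — desk-scale stand-ins for biobank testability.
* **Annotations** — d continuous columns (default 6), the first
  `n_causal_annotations` driving the per-variant impact; decoys are correlated
  with causal columns at a configurable coefficient (default 0.3).
  Consequence classes (pLOF 10%, missense 50%, synonymous 30%, other 10%) are
  drawn independently; pLOF and disruptive-missense status raise, and
  synonymous status lowers, the latent impact in the linear and threshold
  forms, so conventional masks are informative, as in real exomes. CADD is
  simulated to track the true impact noisily. The model consumes the
  continuous columns, the class flags and the transformed MAF.
* **Impact forms** — `linear`: u = σ(scale·(w·a + class terms) + offset);
  `threshold`: a step (0.95/0.02) on the same latent score; `interaction`:
  u = σ(scale·a₁a₂ + offset) with *no* class terms — no single annotation is
  sufficient, which is the regime where a nonlinear set network should beat
  single-annotation burdens.
* **Gene truth** — u_ij is the max of carried variants' u_k (zero for
  non-carriers), matching the model's pooling; threshold and interaction
  variant-level forms allow misspecification studies.
* **Traits** — y = xᵀα + Σ w_j u_ij + ε with Gaussian noise; binary traits
  threshold the liability at a configured prevalence. A trait's
  `variance_fraction` calibrates the noise so the rare-variant component
  explains that share of the genetic-plus-noise variance (covariate effects,
  if enabled, dilute the share of total variance accordingly). Null traits
  (no seed genes) support calibration studies.
* **Covariates** — sex, age, age², age×sex and 10 PC-like standard-normal
  columns.
* Positions are laid out so ~10% of variants fall in the 1–300 bp exon flank
  and ~10% just outside it, exercising both sides of the assignment rule.

What the generator does **not** emulate: linkage disequilibrium, population
structure, relatedness, genotyping error, annotation measurement error
correlated across variants, and gene-size heterogeneity at the Titin scale.
Consequently, passing tests show that the machinery is correct and that the
method's comparative properties hold under its own assumptions — not that the
same effect sizes or yields would be observed in real cohorts.

## Study pipelines (`setrvat.experiments`)

Problem sizes are the package's choice of desk-scale experiments; each runs in
minutes on one CPU and is reproducible from a single seed.

* **Null calibration** — n=4,000, 200 genes; three training traits with ten
  seed genes each (variance fraction 0.4) and twelve pure-null traits; K=2,
  R=1. Seed discovery on null traits is expected to select ~nothing (FWER
  control); association of out-of-fold scores against the null traits over
  ≥2,000 gene–trait pairs yields the empirical type-I error, KS uniformity
  and genomic-control λ.
* **Leaky-pipeline contrast** — n=2,000, 100 genes, ten null traits. The
  deliberately leaky variant selects null-trait "seed genes" at a nominal
  threshold on the full cohort, trains with them, and re-tests exactly those
  genes on the same cohort with in-fold scores; the selection makes the
  retest grossly anti-conservative (λ ≈ 3–4). The proper pipeline
  (FWER-controlled discovery plus out-of-fold scoring) stays at λ ≈ 1.
  Notably, in-fold ψ scoring *alone* produces no measurable inflation at
  these scales: the score test is invariant to affine transformations of the
  burden, and ψ's variance is dominated by carrier status, which is
  phenotype-independent — the dangerous leakage channel in this workflow is
  selection, which is what the safeguards must break.
* **Parameter recovery** — linear truth, n=6,000, two traits with ten known
  seed genes each (variance fraction 0.4), K=2, R=1. Out-of-fold Spearman
  between ψ and the true u over carrier pairs, compared with each single
  annotation.
* **Interaction power** — n=8,000, 60 genes, interaction-only truth, three
  traits with twelve seed genes each (variance fraction 0.5), K=2, R=2.
  True-seed recovery at FWER 0.05 for learned-score testing vs every
  single-annotation max-burden arm vs burden/SKAT combined, plus a
  linear-activation ablation of the module.
* **Prediction** — one trait with three concentrated seed genes at variance
  fraction 0.6 (the regime where extremes are genuinely rare-variant-driven),
  n=10,000 split in half. Discovery, training and gene selection (by
  learned-score association at FWER 0.05) use the training half only;
  R², Relative ΔM = (M_rare − M_PRS)/M_PRS, and deviation-ranked top-1%
  extreme enrichment (bootstrap test of the area above the random baseline)
  are computed on the evaluation half. The common-variant PRS is simulated at
  R² = 0.3 with the trait, standing in for external PRS catalogs. Because the
  simulated gene effects are trait-increasing, enrichment uses top-tail
  labels.

## Numerical and design details

* Quantile transform: Φ⁻¹((rank − 0.5)/n) with average ranks for ties;
  missing values propagate; constant input is an error.
* V_ij is a set of distinct variants — allele count 2 does not duplicate a
  member; dosage is retained separately for the burden/SKAT tests.
* Fold sizes differ by at most one; restart seeds are pure functions of
  (base seed, fold, restart).
* Burden collinear with covariates → p = 1 with a warning rather than an
  error, so genome-wide scans don't abort on degenerate genes.
* AUPRC uses step interpolation (precision as a step function of recall);
  definitions vary, so this one is fixed and cross-checked against a
  reference implementation in the tests.
* Checkpoints carry a version, the layer shapes, the annotation column order
  and the standardisation constants; scoring a cohort whose annotation
  columns differ by name fails loudly.
* Pseudodosage BGEN export implements BGEN v1.2, layout 2, unphased diploid
  biallelic records, uncompressed, 16-bit probabilities; the stored pair is
  (hom-ref, het) with hom-alt implicit, giving round-trip error ≤ 2⁻¹⁶ scale.
* Set scores are exactly invariant at the pooled-embedding level; the final
  scalar may differ across batch layouts by one unit in the last place
  because BLAS may choose different row micro-kernels, so bitwise claims are
  made of the pooling and double-precision claims of ψ.

## Known limitations

* Seed discovery before fold formation mirrors the parent workflow but means
  seed-gene identity is not itself cross-validated; the calibration studies
  show this does not inflate null traits, but seed-gene effect estimates on
  the training traits are optimistic.
* The native logistic score test for binary traits is exact-information but
  not small-sample corrected; treat binary results as screening output.
* The generator's independence assumptions (no LD) make the EAF gate and the
  collapsing rule milder than in real data.
* Training-time determinism holds for a fixed BLAS; across BLAS builds,
  last-bit differences in GEMM can propagate to slightly different
  trajectories.
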