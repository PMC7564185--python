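# Methods

## Signature derivation

Per gene, a two-sample pooled-variance *t* statistic compares the two
training classes (reference class first, so a positive log₂ ratio means
up-regulated in the knockout): t = (m₁ − m₀) / (s_p √(1/n₀ + 1/n₁)) with
df = n₀ + n₁ − 2 and two-sided *p* from the t distribution. Pooled rather
than Welch variance is the default because the compound covariate weights
downstream are classical training t statistics; Welch is available by flag.
Genes pass into the signature when *p* < 0.05 **and** |log₂ ratio| > 0.5.
The fold-change cutoff is applied to the absolute ratio: a knockout
signature contains both induced and repressed genes, and the classifier
needs both directions. No multiple-testing correction is applied at this
stage — the cutoff is a raw-*p* screen whose false positives are controlled
downstream by the weighted sum (a few noise genes with |t| ≈ 2 are swamped
by planted genes with |t| ≈ 18).

Degenerate genes: a gene whose pooled variance is zero while the class means
differ has no finite t; it is excluded with a logged warning. A gene constant
at the same value in both classes is kept with t = 0, p = 1. A gene with
fewer than two non-missing values in either class is dropped and reported.

Cross-species transfer maps gene identifiers through an ortholog table;
the default is case-insensitive symbol matching (mouse *Arid1a* → human
*ARID1A*), which covers the symbol-orthologous majority; a two-column table
overrides it for non-trivial orthology. When two source genes map to one
target, the larger-|weight| entry wins and the discard is logged. Attrition
(unmapped genes, per-cohort overlap, genes shared by all cohorts) is reported
at every step because a mouse signature shrinks substantially by the time it
reaches several human platforms.

## Bayesian compound covariate predictor

Each sample s is reduced to c_s = Σⱼ wⱼ x_js over the signature genes with
wⱼ the training t statistic. The training classes induce Gaussian
class-conditional models with means μ_low, μ_high and a single pooled SD σ
(the classical formulation; an unequal-variance variant sits behind a flag).
With equal priors (the 0.5 posterior cutoff is then symmetric),

P(low | c) = φ((c − μ_low)/σ) / [φ((c − μ_low)/σ) + φ((c − μ_high)/σ)],

evaluated in log space with a log-sum-exp guard so tail samples get exact 0/1
rather than NaN. A sample is called signature-low iff P(low | c) > 0.5
strictly; a posterior of exactly 0.5 goes to signature-high (documented
tie-break, covered by a test).

**Normalization.** Cohorts are median-centered per gene before
classification, and the training matrix is median-centered the same way
before the model is fitted, so the compound covariate lives on a comparable
scale across species and platforms. Centering is idempotent and leaves the
t statistics unchanged (per-gene shifts cancel in the class difference).

**Gene intersection.** When a cohort lacks some model genes the weights are
subset and the Gaussian parameters are *recomputed* by projecting the cached
training expression onto the same reduced gene set. Renormalizing the
weights instead would silently change the covariate's variance and
mis-calibrate σ; recomputation keeps the class model exact for the covariate
actually used. The fitted model therefore carries its training slice in its
(versioned, plain-text) serialization.

**LOOCV.** The leave-one-out loop re-runs the entire procedure — gene
statistics, thresholding, model fit — on each fold's remainder, so gene
selection cannot leak the held-out sample. A fold with an empty signature
counts its sample as misclassified and is logged. On null data this estimator
is known to be pessimistic for very small, imbalance-prone folds; the
permutation test in the suite therefore uses 10 samples per class and judges
the chance rate against the empirical Monte-Carlo spread rather than
independent-Bernoulli SEs.

## Survival

Kaplan–Meier, log-rank and Cox go through lifelines. Cox uses Efron tie
handling (better than Breslow in small samples with ties) and Wald CIs on
the hazard-ratio scale, exp(β̂ ± 1.96 SE), matching the HR/CI reporting
convention of clinical studies. Preconditions enforced here: strictly
positive times, binary event flags, no constant covariates, more samples
than covariates. Time units are whatever the input uses. Overall survival is
the endpoint; a recurrence endpoint is just a second time/event column pair.

## Association and counts

The 2×2 co-occurrence test is Pearson chi-square without Yates correction by
default (the correction is a flag, and a test shows its shrinking effect);
expected counts below 5 raise a warning recommending Fisher's exact test,
which is also exposed (two-sided, hypergeometric). Odds-ratio CIs come from
statsmodels' Table2x2. Other subtype labels are inputs (sample → label TSV),
never re-derived: their classifiers belong to other studies. Published
patient counts used as fixtures are transcribed verbatim, including their
internal inconsistencies (co-occurrence denominators 94 + 153 = 247 against
a cohort n of 242; two cohort sizes swapped between sections of the source
tables); prevalences and row percentages are always recomputed from counts,
never stored.

## Immune scores

IFNG6 is the arithmetic mean of log₂ expression of CXCL9, CXCL10, IDO1,
IFNG, HLA-DRA, STAT1; the cytolytic score the mean log₂ of GZMA and PRF1
(equivalently the log geometric mean of the transcripts — granzyme resolved
to GZMA, the effector paired with perforin in the cytolytic-activity
literature). Averaging on the log scale keeps the scores on the pipeline's
expression scale; the linear-scale alternative is a deliberate non-default.
The 105-gene immunotherapy-response signature (IS) is a required GMT input
scored by z-score averaging (zmean), because its genes span very different
dynamic ranges and the set itself is not redistributable here. Group
comparisons are Welch's t (Mann–Whitney behind a flag); checkpoint genes are
flagged at nominal p < 0.01 with a BH-adjusted column alongside for
transparency, not for the flag.

## Multi-omic correlates

Pearson r over complete pairs (pairwise deletion — protein is typically
observed for only half the samples), p from the t approximation, with an
explicit error on zero-variance input. Chromosomal instability is defined as
the fraction of total segmented genome length with |segment log₂ ratio| >
0.2 — the conventional gain/loss threshold; the metric has no canonical
definition in the clinical literature this emulates, so it is declared,
configurable, and isolated in one function. Methylation is summarized per
gene as mean beta over user-mapped probes. Mutation enrichment reduces per
gene to the same Fisher exact machinery as the association module
(a module-boundary consistency test enforces this); ARID1A variant-class
percentages are recomputed from call counts in the MAF-like input.

## Synthetic-data generator

The generator emulates the study design, not the biology:

* **Mouse experiment** — all genes share one baseline mean (8 log₂ units,
  microarray-like); planted genes shift by ±effect in the knockout class
  (alternating sign so both directions exist); independent Gaussian noise
  per gene on the log₂ scale. Defaults: 1000 genes, 50 planted, effect 4,
  noise SD 0.5, 10 animals per class (group sizes are free parameters of the
  emulated design). Under these conditions the signature threshold recovers
  every planted gene with false positives at the nominal level.
* **Patient cohorts** — the signature genes (uppercased, emulating human
  symbols), background null genes, the immune panels and an ARID1A row;
  signature-low samples (planted fraction 0.4) shift each signature gene by
  4 log₂ units in its recorded direction and the planted immune genes
  (IFNG6, GZMA/PRF1, CD28/CD40/CD226/IL2RB and the CD276/LAG3 pair, the
  latter elevated in the high group as reported) down by 1. Survival is
  exponential with hazard 0.01/month times hazard-ratio 2 for low samples;
  censoring is independent exponential (0.005/month), observed time =
  min(event, censor) — this keeps log-rank/Cox assumptions exactly true, so
  calibration failures indicate implementation bugs, not model
  misspecification. AFP is log-normal with a +0.9 log shift in the low class
  (reproducing ≈60% vs ≈37% exceeding 300 ng/mL); stage is categorical with
  a higher stage-III share in the low class. ARID1A mRNA means are 1.05
  (low) vs 1.27 (high) log₂ units.
* **Multi-omic layer** — protein, gene-level copy number and a latent
  methylation variate are generated as r·z + √(1−r²)·ε against standardized
  mRNA, hitting the population correlation targets exactly (defaults 0.36,
  0.32, −0.22 at the published platform sizes; protein observed for a 181/371
  fraction). Betas are 0.3 + 0.1·latent, clipped to [0,1], plus a +0.1 shift
  in the low group; segment log₂ ratios are noisier in the low group (SD
  0.25 vs 0.15), planting higher instability; mutation flags are per-group
  Bernoulli (e.g. TP53 0.40 vs 0.15). The generator's internal random stream
  is salted so it can never replay a caller's `default_rng(seed)` draws used
  to build the mRNA input.

What the generator does **not** emulate: read-level sequencing noise,
batch/platform effects, gene–gene correlation (noise is independent per
gene), realistic copy-number breakpoint processes, or informative censoring.
Passing tests therefore demonstrate correctness of the estimators and the
pipeline plumbing under the stated model, not robustness to real-data
pathologies.

Seeds are explicit function arguments everywhere (never global state), and
the pipeline spawns per-stage seeds from one config seed via SeedSequence;
identical config + seed reproduces every artifact byte for byte (floats are
written at %.10g, manifests carry checksums and no timestamps).

## Problem sizes

The validation experiments use: 20 seeds for signature recovery; 5
end-to-end replicates for classification agreement; 500 replicates (n = 400,
HR 2, AFP covariate) for Cox CI coverage; 1000 null replicates each for
log-rank and Welch type-I calibration (n = 200 per replicate); 100 seeds at
n = 181 for correlation recovery. These sizes put Monte-Carlo error well
inside the margins being checked (3 SE of a 5% rate at 1000 replicates is
±2.1 points) while keeping a full run in the order of a minute.

## Known limitations

* The cross-species default map is symbol matching; genuine many-to-many
  orthology needs a user table.
* LOOCV's pessimistic small-sample bias is inherent to the re-selection
  design, not corrected.
* The Wald CI for the Cox hazard ratio shows the usual slight under-coverage
  (≈94–95% empirically at n = 400); profile-likelihood intervals are out of
  scope.
* The comparator subtype labeling in the demo is a noisy copy of the planted
  truth, standing in for an external classifier; it exercises the
  co-occurrence machinery, not another signature's biology.
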