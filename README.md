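# arid1a-hcc

Loss of ARID1A — a SWI/SNF chromatin-remodeling subunit and one of the most
frequently mutated genes in hepatocellular carcinoma (HCC) — is hard to read
off directly from tumor genotypes, because mutation, deletion and promoter
hypermethylation all converge on reduced ARID1A *activity*. A
transcriptome-level surrogate sidesteps this: derive an ARID1A-dependent gene
signature from *Arid1a*-knockout mouse liver, carry it across species, and use
it to stratify human tumors into ARID1A-low and ARID1A-high subtypes.

This package implements that pipeline end to end for computational
oncologists and methodologists, together with a synthetic-data generator that
plants known ground truth at every stage, so each statistical step can be
validated by recovery rather than by eyeballing:

1. **Signature derivation** (`signature`): per-gene pooled-variance two-sample
   *t* between wild-type and knockout; genes with *p* < 0.05 and
   |log₂ ratio| > 0.5 form the signature, weighted by their training *t*
   statistics; case-insensitive symbol matching (or a user ortholog table)
   maps mouse genes to human.
2. **Bayesian compound covariate predictor** (`bccp`): each sample is
   projected onto the scalar c = Σⱼ tⱼ xⱼ over signature genes; Gaussian
   class-conditional models N(μ_low, σ²), N(μ_high, σ²) with equal priors
   give P(low | c), dichotomized at 0.5. Validated by leave-one-out
   cross-validation that re-runs gene selection inside every fold.
3. **Survival** (`survival`): Kaplan–Meier curves, log-rank test, and
   multivariate Cox (Efron ties, Wald CIs) of the group indicator adjusted
   for AFP and stage — via lifelines.
4. **Subtype co-occurrence** (`association`): 2×2 cross-tabulation against
   other molecular subtype labelings, Pearson chi-square and Fisher exact.
5. **Immune scores** (`immune_scores`): IFNG6 (mean log₂ of CXCL9, CXCL10,
   IDO1, IFNG, HLA-DRA, STAT1), cytolytic score (mean log₂ of GZMA, PRF1),
   GMT-supplied sets, and per-checkpoint-gene Welch comparisons.
6. **Multi-omic correlates** (`multiomic`): Pearson correlation of ARID1A
   mRNA with protein/copy number/methylation, a chromosomal-instability score
   from SEG segments, and per-gene mutation enrichment by Fisher exact test.

## Worked example

The numbered drivers under `analysis/` run the whole synthetic study
(`cd analysis && python 01_simulate.py && python 02_derive_signature.py &&
python 03_classify_survival.py ...`), or run everything in one call:

```sh
arid1a-hcc run-all --seed 17 --out results/demo
```

Stage output from the drivers at seed 17:

```
signature: 69 genes (31 up / 38 down) at p<0.05, |log2 ratio|>0.5
mouse LOOCV misclassification: 0.000
cohort1: 111/242 signature-low, truth agreement 1.000, log-rank p 0.000178,
         adjusted group HR 2.016 (95% CI 1.432-2.836)
IFNG6: low-group mean 7.01 vs high-group 7.96 (difference -0.96, p = 9.39e-52)
ARID1A mRNA ~ protein: r = 0.29 (n = 111, p = 0.00211)
```

Reading this: the derivation recovered all 50 planted differential genes
(plus threshold-level false positives) from the simulated knockout
experiment; the classifier reproduced every planted cohort label; the
signature-low group's fitted hazard ratio ≈ 2 matches the planted value and
survives AFP/stage adjustment; the planted immune suppression and the planted
protein–mRNA correlation are recovered at their expected magnitudes.

Every CLI subcommand (`simulate`, `derive-signature`, `fit-bccp`, `loocv`,
`classify`, `survival`, `associate`, `immune-scores`, `multiomic`, `run-all`)
is a thin wrapper over the library; all I/O is TSV/GMT/SEG/YAML plain text,
and a checksum manifest makes reruns auditable.

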