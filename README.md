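# ctdnatools

Tools for quantifying circulating tumor DNA (ctDNA) in plasma cell-free DNA
(cfDNA) from targeted panel sequencing, and for predicting — before any blood
is drawn — whether a patient's plasma will contain enough ctDNA for
informative somatic genotyping. The package is aimed at liquid-biopsy
bioinformaticians and translational researchers working on metastatic
castration-resistant prostate cancer (mCRPC) and similar settings where
ctDNA fraction (ctDNA%) drives both prognosis and assay interpretation.

## What it computes

**1. Hierarchical ctDNA-fraction estimation.** Plasma cfDNA is a mixture of
tumor-derived DNA (fraction *t*) and leukocyte-derived DNA. Three convertible
lines of panel-sequencing evidence are combined, in order of preference:

- *Somatic mutation VAFs.* Conservatively assuming every somatic mutation may
  lie in a region of loss-of-heterozygosity (LOH), a clonal mutation has
  expected VAF `t/(2-t)`, so `t = 2/(VAF⁻¹ + 1)`. Sampling noise is handled
  by replacing each observed VAF with its one-sided lower binomial
  (Clopper–Pearson) bound — the VAF the mutation would have if the observed
  count were a 95% quantile outlier. Eligible mutations are autosomal,
  somatic-confirmed, and on non-amplified genes (log-ratio < 0.2); the
  maximum per-mutation estimate (the most plausibly truncal) is adopted.
- *Allelic imbalance of germline heterozygous SNPs* on genes with log-ratio
  evidence of a single-copy deletion (log-ratio in [−0.7, −0.3], ≥ 4 unique
  SNPs per gene): the median major-allele frequency `|0.5 − VAF| + 0.5` is
  inverted through `t = 2 − VAF⁻¹`.
- *Copy-number log-ratios alone* (qualitative fallback), inverting
  `LR = log2((2−t)/2)` for deletions and `LR = log2((2+t)/2)` for low-level
  gains at the class mean.
- An *isolated AR gain* with no other evidence maps to t = 5%, the
  approximate detection floor for the high-level (~7–8 copy) AR gains
  typical of mCRPC; with no evidence at all the sample is *undetected*.

Estimates are bucketed into prognostic categories: undetected (< 2%),
low (2–30%), high (> 30%).

**2. Genotyping-sufficiency prediction.** A gradient-boosted (XGBoost)
framework predicts P(ctDNA ≥ 2%) and a ctDNA% point estimate from routine
clinical variables (cfDNA concentration, PSA, LDH and ALP as ratios to the
upper limit of normal, hemoglobin, liver metastases, ≥10 bone lesions,
ECOG ≥ 2). Tumor-burden markers are monotonically constrained; missing
training values are KNN-imputed (K = 3, unit-variance scaling from the
reference only); hyperparameters are tuned by an adaptive 50%-elimination
grid search inside nested (20×5-fold) cross-validation; and one
classification + one MAE-regression model is trained per non-empty feature
subset (255 pattern pairs for 8 features) so that prediction with partial
inputs never imputes. A dimensionally-weighted K = 20 nearest-neighbor model
with Nelder–Mead-learned weights serves as the simple baseline, and TreeSHAP
attributions explain which variables drive each prediction.

A forward simulator generates read-count evidence at known tumor fraction
and clinical cohorts with a planted burden factor, so everything is testable
without patient data.

## Worked example

```python
import numpy as np
from ctdnatools import estimate_ctdna_fraction
from ctdnatools.simulate import ReadSimConfig, simulate_sequencing_sample

muts, snps, cn, truth = simulate_sequencing_sample(
    ReadSimConfig(true_fraction=0.50, depth=2000, seed=1)
)
est = estimate_ctdna_fraction(muts, snps, cn)
print(f"true t = {truth['true_fraction']:.2f}")
print(f"estimate = {est.fraction:.4f}  tier={est.tier}  category={est.category}")
print(f"mutation evidence: {est.n_eligible_mutations}, "
      f"LOH genes: {est.n_eligible_genes}, concordant: {est.concordance_flag}")
```

prints

```
true t = 0.50
estimate = 0.4864  tier=mutation  category=high
mutation evidence: 7, LOH genes: 2, concordant: True
```

i.e. at 2000× depth the estimator recovers a true 50% tumor fraction to
within 1.4 percentage points (the small downward bias is the deliberate
price of the conservative binomial correction), the mutation tier took
precedence over the SNP-imbalance tier, and the
orthogonal SNP-imbalance estimate agreed within tolerance. The same
workflow is available from the shell:

```bash
ctdna --seed 1 simulate-reads --fraction 0.3 --out-prefix sim
ctdna estimate --mutations sim.mutations.tsv --snps sim.snps.tsv \
      --copy-number sim.copy_number.tsv --out estimates.tsv
ctdna --seed 1 simulate-cohort --n 300 --out cohort.csv
ctdna --seed 1 train --cohort cohort.csv \
      --features cfdna_conc,psa,ldh_uln --num-round 50 --out-dir bank/
ctdna predict --model-dir bank/ --input patients.csv --out predictions.csv
```

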