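# Methods

## ctDNA-fraction estimation

Plasma cfDNA at tumor fraction *t* mixes tumor genomes (which may carry a
mutation on every remaining allele after LOH) with diploid normal genomes.
The estimator's forward models, each invertible in closed form:

| evidence | forward model | inversion |
|---|---|---|
| somatic mutation under LOH | VAF = t/(2−t) | t = 2·VAF/(1+VAF) |
| somatic mutation, diploid het | VAF = t/2 | (not used for estimation) |
| het SNP on single-copy deletion | HSAF = 1/(2−t) | t = 2 − 1/HSAF |
| single-copy deletion depth | LR = log2((2−t)/2) | t = 2 − 2^(LR+1) |
| single-copy gain depth | LR = log2((2+t)/2) | t = 2^(LR+1) − 2 |

All somatic mutations are treated as potentially LOH-associated. This is
deliberately conservative in both directions: for a truly diploid-het
mutation the LOH inversion *underestimates* by roughly a factor of 2 at low
*t*, but taking the maximum over mutations selects the most truncal signal,
and the binomial correction (below) guards the maximum against sampling
noise.

**Binomial outlier correction.** The observed mutant count k at depth n is
treated as a potential upper-quantile outlier: the corrected VAF is the p
solving P(X ≥ k | Binomial(n, p)) = 0.05, i.e. the one-sided lower
Clopper–Pearson bound, computed exactly as `beta.ppf(0.05, k, n−k+1)`. It
is always ≤ k/n (equality only at k = 0) and converges to k/n as n grows,
so the correction matters exactly where sampling noise does.

**Eligibility rules.** Mutations: somatic-confirmed (upstream paired
tumor/leukocyte calling removes germline and clonal-hematopoiesis variants;
this package only consumes the flag), autosomal (sex-chromosome VAFs have a
different mixture model in males), host gene not amplified (log-ratio
< 0.2); a missing host-gene log-ratio counts as non-amplified but is
flagged, since excluding it would discard most evidence on panels without
full copy-number coverage. SNP-imbalance genes: log-ratio in [−0.7, −0.3]
(both ends inclusive) and ≥ 4 unique heterozygous SNPs. The per-gene
statistic is the *median* major-allele frequency, robust to a single
miscalled genotype; the overall SNP-tier estimate is the maximum over
eligible genes, mirroring the mutation tier's most-truncal rationale (an
open design point — multi-gene aggregation is not otherwise determined).

**Hierarchy.** mutation → SNP-imbalance → qualitative log-ratio fallback →
isolated-AR-gain heuristic (5%) → undetected (0). When both of the first
two tiers produce estimates, a concordance flag records agreement within
0.15 absolute; discordance is only flagged, never auto-resolved. A
sub-detection mutation-tier estimate (< 2%) keeps its numeric value but is
categorized undetected. The qualitative gain class is capped at log-ratio
0.58 (≈ 3 copies at purity 1) and excludes AR, whose isolated gain has its
own tier: an AR gain visible on depth data rules out ctDNA < 2%, and 5% is
the approximate detection floor of the ~7–8-copy AR amplifications typical
of castration-resistant disease.

**Categories.** [0, 2%) undetected, [2%, 30%] low, (30%, 1] high. The 30%
boundary is assigned to "low" (the convention of the cohort tables this
mirrors; the alternative "30–100% = high" reading conflicts and was not
adopted). 2% tracks the mutation limit of detection of contemporary
genotyping panels; 30% the limit for single-copy deletions.

## Read-count simulator

`simulate_sequencing_sample` draws per-entity depths from a negative
binomial (mean = target coverage, dispersion 20 by default) to mimic
capture variability, then binomial read counts at the forward-model
probabilities above, and Gaussian log-ratio noise (σ = 0.05). The truth
record carries every expected value. It does **not** model sequencing
error, strand artifacts, fragment-length effects, subclonality, or
whole-genome doubling — so parameter-recovery tests demonstrate correctness
of the inversion chain under the model's own assumptions, not robustness to
assay artifacts. Recovery tests use depth 2000 and 5 LOH mutations per
sample (t ∈ {0.05…0.8}, 50 seeds), sizes chosen to match deep targeted
panels while keeping the suite fast.

Note the estimator's deletion window [−0.7, −0.3] implies the SNP tier only
activates for t ≳ 0.37 (single-copy deletion at t = 0.3 gives LR ≈ −0.23);
at lower fractions the mutation tier carries the estimate, which matches
how the tiers are meant to interact.

## Clinical-cohort simulator

A single latent burden factor z ~ N(0,1) drives everything. The label is a
left-censored logit-normal: fraction = expit(μ + σz) with μ = logit(0.05),
σ = 2.64, censored to 0 below 2%. These defaults put the median near 5%,
the undetectable mass near 36–38% and the >30% mass near 20% — the shape of
real first-line mCRPC cohorts — but they are config fields, not truths the
tests assert. Each serum marker is a monotone transform (log-normal for the
right-skewed markers, linear for hemoglobin) of its own latent
u = ρz + √(1−ρ²)ε; loadings are calibrated through ρ = 2·sin(π·ρₛ/6) so the
implied Spearman correlation with the label matches a configured target
(0.55 for cfDNA concentration, 0.40–0.41 for PSA/LDH, negative for
hemoglobin). Binary features threshold their latent at a configured
prevalence. Missingness is completely at random — a simplification; real
clinical missingness is likely informative — so imputation tests validate
mechanics, not MNAR robustness. The label being a deterministic function of
z means a latent oracle would classify perfectly; feature noise alone
limits achievable AUC.

## Sufficiency prediction

**Label.** ctDNA ≥ 2%, the limit of detection for mutations on large
targeted panels; the same threshold defines the KNN baseline's neighbor
vote.

**Imputation.** K = 3 nearest reference rows after scaling every dimension
to unit standard deviation, statistics from the reference table only.
Distance is the root-mean-square difference over mutually observed scaled
dimensions (RMS rather than a raw sum so rows with different numbers of
shared dimensions stay comparable). Missing cells take the neighbor mean
(mode for binary/categorical — the mean of level codes would be
meaningless). Median imputation was rejected because it drags incomplete
samples toward the cohort average; XGBoost's sparsity-aware default was
rejected because its behavior is unpredictable when a feature is dense in
training but sparse at prediction time.

**Models.** XGBoost with binary logistic objective (classification) or MAE
objective (regression). cfDNA concentration, PSA, LDH and ALP are
constrained monotone non-decreasing; hemoglobin is left unconstrained (its
negative association is real but was not part of the constrained set).
`colsample_bytree = colsample_bylevel = subsample` per candidate to keep the
grid tractable. `tree_method="exact"`, one thread, fixed seed — bitwise
reproducible.

**Tuning.** Grid: num_round ∈ {10,20,50,100,200,500}, max_depth ∈ {2..8},
eta ∈ {0.005,0.01,0.02,0.05,0.1}, subsample ∈ {0.25,0.5,0.75} (630
candidates). Adaptive search: every surviving candidate is scored on
identical K-fold splits (so ranking is unaffected by split sampling), by
mean AUC across folds (mean-across-folds rather than pooled — a deliberate
choice where either reading is defensible); the bottom half is dropped
(keep = ⌈n/2⌉, ties broken by candidate order) and the repetition count
doubles, starting at 1 and capped at 16. Regression candidates rank by
negative MAE.

**Nested CV.** 20 outer × 5 inner folds by default. Per outer fold the
training rows are imputed against themselves, the test rows against the
training rows only, tuning sees only the training rows, and the report's
`state_hash` digests exactly the training-side state (imputed matrix,
scaling, winning hyperparameters) so leakage is checkable by recomputation.
PPV/NPV are reported at probability 0.5 (no threshold was otherwise
specified).

**Pattern bank.** One classifier + one MAE regressor per non-empty feature
subset (2^k − 1; 255 for the 8-feature default; capped at k = 12). Training
imputes once over the full declared panel (all columns give context), then
restricts columns per pattern. By default hyperparameters are tuned once on
the full-feature pattern and reused bank-wide — tuning 255 patterns
independently multiplies cost ~255× for marginal benefit on subsets of the
same cohort; `tune="per_pattern"` is available when that cost is
acceptable. Prediction routes a record to the exact-pattern model and never
imputes; regression output is clipped to [0,1].

**Default feature panel** (all configurable): cfDNA concentration (ng/mL),
PSA (ng/mL), LDH and ALP as ratios to the local upper limit of normal
(making the model portable across laboratories with different reference
ranges), hemoglobin (g/L), liver metastases, ≥10 bone lesions, ECOG ≥ 2.
The panel reflects the strongest burden correlates; exact historical
feature lists are not part of this package's contract.

**Weighted-KNN baseline.** K = 20; point prediction = median neighbor
label; probability = neighbor fraction ≥ 2%; missing dimensions omitted
from the weighted Euclidean distance. Weights (squared optimizer variables,
hence non-negative; features pre-scaled to unit variance so the simplex
starts comparably) minimize leave-one-out MAE via Nelder–Mead. Because the
LOO objective is piecewise constant in the weights, a single simplex can
stall on a plateau; the fit runs a few perturbed restarts and keeps the
best, and non-finite excursions also trigger a restart.

**Attribution.** Exact TreeSHAP as built into XGBoost (`pred_contribs`):
per-sample additive contributions plus baseline reproduce the margin
exactly (additivity is asserted to 1e−6 in tests). Reports aggregate the
mean contribution per level (categorical/binary) or per quartile
(continuous).

## Numerical and degenerate-input choices

- VAF is recomputed from counts; a supplied column disagreeing by > 1e−6 is
  an error (stale-column guard).
- All ties (neighbor distances, candidate scores) break by deterministic
  order; every stochastic component is seeded.
- Zero-depth mutations are skipped by the estimator; zero-read SNPs are
  invalid at parse time.
- A table row sharing no observed dimension with any reference row is a
  hard error, not a silent fallback.
- Single-class training labels raise immediately rather than producing a
  degenerate classifier.

## Known limitations

- No whole-genome-doubling correction: aneuploid genomes inflate somatic
  allele frequencies and the estimator will overestimate t.
- No subclonality model: the max-over-mutations rule assumes the top
  mutation is clonal.
- The simulators omit sequencing error, CHIP variants, fragmentomics and
  informative missingness; passing recovery tests certify the estimation
  arithmetic, not assay robustness.
- The cohort simulator's single-factor structure makes all burden markers
  mutually correlated through z; real cohorts have richer correlation
  structure.
- Estimation below ~2% is reported but not trustworthy (the detection
  category exists precisely for this).
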