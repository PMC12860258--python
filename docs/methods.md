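# Methods

`steroidscope` re-implements, as a tested pipeline over synthetic data, the
computational analysis used in adrenal-tumour steroid metabolomics: 24-h
urinary steroid profiles of patients with non-functioning adrenal tumours
(NFAT), mild autonomous cortisol secretion graded by the 1 mg overnight
dexamethasone suppression test (MACS-1: 51–138 nmol/L; MACS-2:
>138 nmol/L), and adrenal Cushing's syndrome (CS), together with an
untargeted serum metabolome arm. Because patient-level data from such
studies are shared only on request, every stage is exercised end-to-end on
a generator that reproduces the statistical structure the methods assume;
the published cohort's categorical arithmetic is recomputed exactly from
its printed per-group counts.

## The steroid panel

Seventeen urinary steroid metabolites quantified by LC-MS/MS:
glucocorticoids and their tetrahydro-metabolites (cortisol, cortisone,
THF, 5α-THF, THE, α/β-cortol, α/β-cortolone), precursor metabolites (THS,
PD, PT, 5-PT), classic androgen metabolites (androsterone,
etiocholanolone, DHEA) and 11β-hydroxyandrosterone, the major urinary
metabolite of the adrenal 11-oxygenated androgens. The panel membership is
the package's own reconstruction of the field-standard profiling panel
(the defining publication lists it only in an appendix); column names are
canonicalised against this list at read time so unknown metabolites are
rejected rather than silently propagated.

## Prototype classification (GMLVQ and ordinal LVQ)

Both classifiers learn one prototype per class and a global metric
d(x,w) = (x−w)ᵀΛ(x−w) with Λ = ΩᵀΩ and trace(Λ) = 1, so diag(Λ) is a
relevance profile over features that sums to one. The cost is the GLVQ
statistic μ = (d_J − d_K)/(d_J + d_K) summed over samples (d_J, d_K:
distances to the nearest correct / wrong prototype). The ordinal variant
multiplies each term by the absolute rank distance between the sample's
class and the class of the competing prototype, so mislabelling NFAT as CS
costs three times as much as mislabelling it as MACS-1; with two classes
the weight is constant and the two classifiers coincide exactly (the test
suite asserts bit-identical trajectories).

Optimisation is full-batch gradient descent on prototypes and Ω with
exponential annealing (default rates 0.05/0.05 over 300 epochs) and step
halving whenever the cost would rise, which makes the recorded cost trace
non-increasing — the property the tests enforce. Batch steps were chosen
over per-sample updates because they vectorise (the consensus stage trains
2 classifiers × M imputations × runs) and make the halving heuristic
well-defined. Ω is renormalised to unit Frobenius norm after every step.

Ω may be rectangular (`omega_rank`). In low-rank mode the transform is
initialised from the between-class scatter directions plus small seeded
jitter: a random rank-2 projection of a 2000-feature space carries
essentially no class signal, and batch training cannot recover from it
(train CCR ≈ chance, relevances uniform); seeded from the class-mean
subspace the same data recover the planted informative features. Full-rank
mode keeps the identity initialisation that is standard for GMLVQ.
Prototypes start at class means plus jitter of 0.05 feature-SDs.

Reported performance uses repeated stratified 90/10 holdout (default 30
runs, fresh split and training seed per run), collecting per-run
relevances (the violin data), validation CCR/AUROC, and per-class
prototype vectors (mean ± SD across runs). The binary AUROC score is the
signed normalised distance difference (d_neg − d_pos)/(d_neg + d_pos);
confidence intervals are stratified bootstrap percentiles (2000
resamples). The 2-D embedding projects samples and prototypes onto the
top-2 eigenvectors of Λ scaled by the square root of their eigenvalues,
with a deterministic sign convention.

Steroid matrices are log-transformed and z-scored per metabolite before
training; zeros are replaced by half the smallest positive value.

## Double GMLVQ (discriminative subspace emersion)

To ask which steroids discriminate a clinical co-label (hypertension,
type-2 diabetes, bilateral tumours) beyond the diagnostic-group structure:
stage 1 trains GMLVQ on NFAT-vs-MACS and eigendecomposes Λ₁; the data are
deflated by the projector onto the orthogonal complement of the top-r
eigenvectors, with r the smallest number of directions holding ≥95 % of
trace(Λ₁); stage 2 trains GMLVQ on the clinical flag in the complement,
over 30 seeded runs, and its relevances are mapped back to the original
axes as diag(PΛ₂P), renormalised. The projector is exactly idempotent and
symmetric, and annihilates the deflated directions, by construction;
planted signals orthogonal to the primary axis are recovered as top
secondary relevance, while signals living inside the primary subspace
become unpredictable (held-out accuracy at chance) after deflation.
Whether the published method composes the two metrics differently cannot
be settled from the main text; the deflation construction is this
package's documented reading, and the r-selection rule is config-exposed.

## Sympercent regression and cohort summaries

Each steroid is regressed (OLS) on the binary contrast of interest plus
age, sex (F=1) and BMI after natural-log transformation; 100 × the
contrast coefficient is a *sympercent*, a percentage change symmetric in
direction (swapping the contrast coding flips the sign exactly; scaling a
steroid by any constant leaves it unchanged). CIs are normal-theory
coefficient CIs × 100; p-values are reported unadjusted across the 17
models. The cohort summary reproduces clinical "Table 1" conventions:
per-group n, % women (1 decimal, round-half-even), median (IQR) age and
BMI, comorbidity prevalences, pooled MACS and Total rows, with one-way
ANOVA (numeric) and chi-square (categorical) trend tests; a category that
is entirely absent in some group (e.g. 100 % women) leaves the chi-square
undefined and is reported as NaN.

## Untargeted preprocessing

Fixed, enforced order — drift correction, quality filtering,
normalisation:

* **QC-RSC drift correction.** Per feature, a cubic smoothing spline of
  pooled-QC intensity over injection order (smoothing chosen by GCV, the
  standard rotation-invariant approximation to leave-one-out CV), made
  robust by three Tukey-bisquare reweighting iterations; fewer than 4 QCs
  falls back to linear interpolation. Intensities are divided by the
  spline and rescaled by a reference level chosen so the per-feature QC
  median is exactly invariant. Features whose spline dips non-positive are
  left uncorrected with a warning.
* **Quality filters.** Features are removed when QC RSD (100·sd/mean,
  post-correction) exceeds 30 % or QC detection falls below 90 %; values
  exactly at the boundaries are kept, mirroring the strict inequalities of
  the stated rule. Filtering is idempotent.
* **Normalisation.** Natural log, then per-feature z-score using study
  samples only (n−1 denominator); non-positive cells become missing,
  zero-variance features are dropped.

## PPCA multiple imputation

Missing cells are imputed under probabilistic PCA, x = μ + Wt + ε with
isotropic noise, fitted by EM that treats both latent scores and missing
cells as latent variables; the observed-data log-likelihood is evaluated
each iteration via the Woodbury identity and is non-decreasing (enforced
to 1e-8 relative tolerance; EM stops cleanly if σ² collapses to its floor
on effectively noise-free data). Initialisation is mean-impute + SVD; the
latent dimension defaults to the smallest k explaining ≥80 % of variance
on complete columns (config-exposed, as is M; default M = 10 imputations).
Each imputation draws the missing cells of each row from the exact
Gaussian conditional given that row's observed cells (sampled through the
latent posterior, so no large covariance is ever formed); observed cells
are bit-identical across draws.

The generator's missingness is intensity-dependent (MNAR) while PPCA
assumes ignorable missingness — an intentional, documented mismatch
mirroring real practice, stress-tested by the recovery suites.

## Consensus selection, fold changes, association

GMLVQ and ordinal LVQ are trained on every imputed matrix (repeated runs,
rank C−1 Ω); features are ranked by mean relevance per matrix. A feature
is consistent for a classifier when it is in the top-500 of *every*
matrix (a relaxed quantile is config-exposed); the informative set is the
intersection of the two classifiers' consistent sets, with full Venn
accounting. Training seeds are held fixed across matrices so that
between-matrix ranking differences reflect imputation variability alone.
Fold changes of selected features are mean log2 differences vs NFAT,
summarised per annotation class (median, IQR, 5th–95th centile; all /
increased-only / decreased-only strata); classes with fewer than 20
selected features are omitted from summaries, not from selection.

Steroid-feature association is Spearman correlation (midrank ties,
t-approximation p-values) across the top-5 steroids × consensus features,
BH-adjusted jointly with significance at q < 0.05 (the threshold is the
package's choice; the source reports none). Pathway over-representation
is the upper-tail hypergeometric test on a user-supplied annotation map,
BH-adjusted across pathways. Because the p-values are discrete, the test
suite checks validity as exactness at the discrete support (super-uniform
elsewhere) rather than a naive continuous-uniform KS test.

## The synthetic-data generator

What it emulates, with defaults chosen once as the study conditions:

* cohort sizes 104/70/70/47 (untargeted arm; the steroid-profiling arm is
  generated at 649/451/140/65), women fractions, group-specific age
  distributions, DST cortisol drawn inside each group's defining window;
* log-normal steroid excretion: ln(steroid) = baseline + group gradient +
  sex/age/BMI terms + N(0, 0.5²); glucocorticoid and THS gradients rise
  strictly NFAT→CS (up to 1.0 log-units), classic androgens fall,
  11β-hydroxyandrosterone stays exactly flat;
* hypertension and type-2-diabetes labels from logistic models on z-scored
  log glucocorticoids and 11β-hydroxyandrosterone, so refitting recovers
  the coefficient signs at n = 400/group;
* a 2000-feature table with rank-5 latent structure, 50 informative
  features with graded, sign-alternating shifts (1.0 log-units at CS),
  their lipid-class labels skewed towards glycerophospholipids
  (50/20/12/8/6/4 % across the six classes, as in real lipidome
  perturbations) while background features spread evenly, smooth
  sinusoid-plus-linear multiplicative drift over injection order,
  pooled-QC rows (per-feature study mean + 5 % analytical noise) evenly
  interleaved in the run, and logistic-in-log-intensity missingness
  applied to study cells (~15–20 % missing at defaults).

Pooled QCs are modelled as detected: QC material sits at each feature's
typical concentration, and the quality filters are exercised by planting
failing features explicitly rather than by random QC dropout. Determinism
is a contract: one master seed, per-stage fixed offsets, bit-identical
outputs for identical configs.

What it does **not** emulate — and what passing tests therefore do not
show about real data: realistic lipid nomenclature or annotation error,
batch effects across assays and ion modes beyond a single smooth drift,
correlated missingness mechanisms other than intensity censoring, and the
real cohort's effect sizes (the published classification numbers, e.g. a
38.7 % four-class correct classification rate and an NFAT-vs-MACS AUROC
of 0.75, depend on the real data and are not reproduction targets; the
synthetic analogues land wherever the chosen gradients put them).

## Numerical choices and problem sizes

EM tolerance 1e-6 relative, max 500 iterations; LVQ cost-tie epsilon
1e-300 guards exact-zero distances; percentage rounding is half-even;
bootstrap CIs use 2000 resamples. The test suite and acceptance script run
the untargeted chain at the study's 2000-feature scale once and smaller
configurations elsewhere (300–400 features for drift and recovery checks;
scaled run counts, runs=5 and M=3, where the full 30×10 protocol would add
nothing but time). The pipeline orchestrator derives stage seeds from the
config's master seed and writes SHA-256 digests of every output so
deterministic stages can be verified digest-for-digest on rerun.

## Known limitations

The ordinal cost's exact published form is an appendix-level detail of its
source; the rank-weighted GLVQ cost used here is one defensible reading,
flagged as such. The deflation reading of double GMLVQ is likewise the
package's own. Relevance profiles of correlated features are not unique —
high relevance does not imply a large univariate mean difference, and the
tests deliberately assert recovery of planted signals rather than
univariate effect ordering.
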