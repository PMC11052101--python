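# Methods

This note documents the statistical model behind the package, the synthetic
cohort generator's assumptions, the numerical choices, and the limits of
what the test suite demonstrates.

## The prediction problem

The target is resting metabolic rate (RMR, kcal/day) in women with
lipedema, measured by indirect calorimetry through the Weir equation
REE = (VO₂·3.941 + VCO₂·1.11)·1440 with VO₂/VCO₂ in L/min. The twelve
predictors are age (years), height (cm), weight (kg), BMI (kg/m²), lean
body mass LBM (kg), percent body fat PBF (%), mass of body fat MBF (kg),
total body water TBW (kg), Tanita visceral fat level VFL (ordinal), waist
(cm), hips (cm) and waist-to-hip ratio WHR. Four of them are deterministic
functions of the others (BMI = weight/(height/100)², WHR = waist/hips,
MBF = PBF/100·weight, LBM = weight − MBF), so the design matrix is severely
multicollinear by construction and classical multiple regression is
ill-posed. The pipeline therefore screens with VIF, reduces dimension with
correlation-matrix PCA, and regresses RMR on the retained component scores.

## Pipeline components

**Standardization.** All descriptive statistics and the in-pipeline
standardization use the sample SD (n − 1 denominator); one convention is
applied everywhere.

**VIF.** VIF_j = 1/(1 − R²_j), where R²_j comes from the OLS regression
(intercept included) of predictor j on the other eleven. Exact collinearity
(1 − R² below 1e−12) is reported as +inf and flagged rather than raised:
detecting it is the screen's purpose. VIF > 10 is the flagging criterion.

**PCA.** Eigendecomposition of the sample correlation matrix, computed as
the SVD of the standardized data matrix (numerically stabler than forming
and decomposing the Gram matrix; the two coincide because the data are
standardized first). Loadings are unit eigenvectors with a deterministic
sign convention: the largest-magnitude entry of each component is positive.
Retention is Kaiser's rule (eigenvalue > 1) or a cumulative
explained-variance threshold. cos2(variable, component) =
(loading · √eigenvalue)², the squared correlation between variable and
component; each variable's cos2 sums to 1 over all twelve components.

**Score conventions.** Two conventions for "standardized PC scores"
coexist:

* *standard* — loadings applied to standardized variables, scores divided
  by √eigenvalue. This is the textbook projection and is what the
  derivation pipeline uses.
* *raw* — loadings applied to raw predictor values, then affinely
  standardized by the training cohort's raw-score mean and SD. The
  published equation's score formulas are written this way (its component
  means ≈ 109 and SDs ≈ 34.5 can only arise from loadings times raw
  measurement values), so the published-equation path implements it
  verbatim.

The two conventions are *not* affinely equivalent per component — their
gradients with respect to a subject differ by the per-variable SDs — and
the published source is internally ambiguous about which applies (its
loading table is labelled as acting on standardized variables while its
score formulas apply the same numbers to raw values). The package keeps
both explicit rather than resolving the ambiguity silently.

**Learners.** Five learners map the three retained scores to standardized
RMR, with the published hyperparameters as presets: SVR (C = 1, polynomial
kernel, degree 1), random forest (200 trees, max depth 10, sqrt features,
min samples leaf 4 / split 2, bootstrap), k-NN (6 neighbours, uniform
weights), ridge (alpha = 1e−4), and the segmented model (branch C = 1.5
below / C = 1 above). SVR epsilon (0.1), gamma ('scale') and kernel offset
(0) were not published; these defaults are the package's documented choices
and are overridable.

**Segmented model and closed-form extraction.** The modelling dataset is
split at the median (linear interpolation for even n) of standardized RMR;
this threshold is computed on the *full* dataset before the train/test
split, making the split rule predetermined. Each side gets its own degree-1
polynomial-kernel SVR. Because that kernel is affine, the decision function
Σᵢ αᵢ(γ⟨xᵢ,x⟩ + c₀) + b reduces exactly to weights γ·Σᵢαᵢxᵢ and intercept
b + c₀·Σᵢαᵢ. The lower branch's linear form, compared to the threshold,
gates new subjects; ties (=) go to the lower branch, matching the printed
inequality. A constant target degenerates gracefully (both branches fit the
constant).

**Model selection.** One random 90/10 train/test split (test size =
⌈0.1·n⌉), 5-fold cross-validated grid search with folds formed as
contiguous blocks after a seeded shuffle. Candidates are scored by mean
fold-out MAPE on the kcal/day scale — predictions are back-transformed
before scoring, since MAPE on standardized targets is meaningless near
zero; the published procedure reports MAPE on non-standardized data, and
that choice is extended to CV scoring. Ties break toward the earlier grid
candidate.

**Evaluation.** MAPE = 100·mean(|measured − predicted|/|measured|).
Bland–Altman differences are oriented predicted − measured (positive =
overestimation); limits of agreement are mean ± 1.96·SD (n − 1). No
proportional-bias regression or LoA confidence intervals.

**Published equation.** All printed constants are kept exactly, including
two discrepancies surfaced as machine-readable caveats: the gate weight on
PC1st (0.0482) differs from branch 1's prediction weight (0.0472), making
the prediction discontinuous at the gate; and the back-transform RMR mean
(1693.5234) differs from the cohort-table RMR mean (1685.8). Whether either
is a typographical artifact cannot be determined from the source; neither
is "corrected".

## Synthetic cohort generator

The clinical data are not public, so the generator emulates the cohort's
published summary statistics and the structure the pipeline assumes:

* **Marginals.** age ~ N(43.4, 13.4²), height ~ N(165.5, 6.8²) (cm),
  weight ~ N(87.5, 21.8²) (kg), PBF ~ N(37.7, 7.3²) (%), waist ~
  N(96.5, 17.5²), hips ~ N(115.6, 13.6²) (cm), VFL ~ N(12.7, 5.1²) rounded
  to an integer level in [1, 59]. Truncation at mean ± 4 SD with physical
  floors (weight ≥ 30 kg, waist ≥ 50 cm, age ≥ 0); the floors trim under
  1% of each marginal and shift means by well under 1%, preserving the 2%
  calibration contract. Sampling is exact inverse-CDF truncated-normal
  from a single seeded stream, so a fixed seed gives a bit-identical
  cohort.
* **Dependence.** A single standard-Gaussian adiposity latent A drives
  weight, PBF, waist, hips and VFL with loadings 0.9·SD (0.85·SD for PBF);
  each variable adds an independent residual so its marginal SD is
  preserved. One shared latent is the minimal structure that yields both
  the realistic weight–waist–PBF–VFL correlations and the low effective
  rank that makes a few principal components dominate. The real covariance
  matrix was never published; the loadings are calibration constants, not
  estimates.
* **Identities.** BMI, WHR, MBF, LBM are computed exactly from their
  definitions, which reproduces the qualitative VIF finding (weight, LBM,
  MBF exactly collinear, hence infinite VIF; BMI far above 10). TBW =
  0.73·LBM (the standard hydration fraction of lean mass) plus a 1.5 kg
  residual.
* **RMR.** Cunningham-like linear model: 21 kcal/day per kg LBM, 4 kcal/day
  per kg MBF, −2 kcal/day per year of age, Gaussian noise SD 110 kcal/day.
  The intercept (≈ 516.6) is solved in closed form so the untruncated
  population mean equals the cohort's 1685.8 kcal/day, using
  E[MBF] = (μ_PBF·μ_weight + λ_PBF·λ_weight)/100 and E[LBM] = μ_weight −
  E[MBF]. The implied RMR SD (≈ 270 kcal/day) lands near but below the
  cohort's printed 310 kcal/day; the mean, not the SD, is the calibration
  contract.

**What the generator does not emulate.** The real cohort's tail shape (it
reported 74.8% overweight/obese, which a Gaussian BMI marginal cannot match
exactly — proportions are not calibration targets), its true covariance
structure beyond the single-latent approximation, its printed LBM summary
(48.7 ± 19.8 kg, which is inconsistent with LBM = weight − MBF ≈ 53 kg
under the printed weight and MBF means; LBM is treated as derived and its
printed SD is not forced), measurement-device quirks, or any non-Gaussian
or nonlinear physiology. Consequently, pipeline results on synthetic
cohorts validate the *procedure* — its determinism, its algebra, its
qualitative behaviour — not the published error rates: the published
per-model MAPEs (10.78–15.92%) depend on the unpublished clinical data and
are out of reach by design.

## Numerical choices and degenerate inputs

* Strict cohort validation enforces the identities up to rounding
  tolerances (0.1 kg/m² BMI, 0.01 WHR, 0.5 kg masses) and is opt-in,
  because tables of rounded instrument outputs routinely violate exact
  identities.
* CSV output prints 10 significant digits; read/write round-trips are
  exact to well beyond 6 significant digits.
* Exact collinearity in VIF: 1 − R² < 1e−12 → +inf.
* PCA with fewer records than predictors warns and returns the
  rank-deficient decomposition (trailing zero eigenvalues).
* Equation JSON serialization is key-sorted with full-precision floats;
  repeated runs under a fixed seed are byte-identical.
* The parameter-recovery test of the segmented machinery uses epsilon =
  1e−3 and C = 100 instead of the presets: the preset epsilon (0.1
  standardized units) is an insensitivity *tube* an order of magnitude
  wider than that scenario's 1% noise, so it deliberately does not
  interpolate; the recovery test probes the fitting/extraction algebra,
  not the presets.
* Test problem sizes (119-subject study-sized cohorts, a 100,000-subject
  calibration draw, 2,000-subject recovery scenarios) are chosen so the
  whole suite runs in well under a minute while keeping Monte-Carlo error
  far inside the asserted tolerances.

## Known limitations

* The published equation is implemented as printed; its gate discontinuity
  and its two-constant ambiguity (0.0482/0.0472) are inherited, not
  resolved.
* The raw-score projection convention makes the three published component
  scores strongly mutually correlated (all are dominated by the large-scale
  size variables); this is faithful to the source, not a property of PCA.
* Derived equations are cohort-specific: loadings, score affines and
  thresholds all re-estimate on new data, and nothing here validates
  transfer to other populations.
* knn and random-forest fits have no closed form; only degree-1 SVR and
  ridge support equation extraction.
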