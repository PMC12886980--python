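# Methods

This note records the statistical model, the generator's assumptions, the
numerical choices, and the limits of what the shipped tests demonstrate.

## Derived scores and thresholds

All classification rules are threshold rules collected in
`ThresholdPolicy`, with boundary conventions chosen to match their clinical
definitions: stunting at HAZ ≤ −2 (inclusive), severe at ≤ −3 (inclusive);
anemia strictly below 11 g/dL hemoglobin (altitude-adjusted values are
expected as input — the adjustment itself is out of scope); ferritin
multiplied by 0.67 only when CRP is strictly above 6 mg/L, low below
12 µg/L; CRP elevated strictly above 10 mg/L; citrulline low below 7 and
elevated above 43 µmol/L (7.0 and 43.0 are "normal"); qPCR gene presence at
Ct strictly below 37; fecal α1-antitrypsin normal strictly below
1.25 mg/g dry weight or 0.15 wet weight; dietary diversity 0–7 with low
diversity strictly below 4. The three-level socioeconomic category
implements exactly the published decision rules (no telephone or
pounded-earth floor → 1; telephone + solid floor + internal shower or
separate internal kitchen → 3; else 2); the upstream asset PCA that
originally produced those rules is not re-derived. Reported percentages use
round-half-up to one decimal, which reproduces every printed value; the
underlying convention was not stated, so this is a package choice.

## The synthetic cohort generator

The generator exists so that every downstream stage — scores, regressions,
constructs, SEMs — can be exercised against known ground truth without any
restricted data. It emulates a cohort of 349 children aged 24–60 months.

Structure (all latents on standardized scales):

- `SES`, `BCAA`, `hb_z` ~ N(0,1), independent.
- diversity driver `d = 0.10·SES − 0.30·BCAA + ε(0.95)` — BCAA levels
  depress gut diversity, SES mildly raises it.
- `HAZ = −1.75 + 0.30·SES + 0.25·hb_z + 0.20·BCAA + 0·d + ε(1.0)`,
  rounded to 2 decimals and categorized; the −1.75 location and the implied
  total SD ≈ 1.1 put roughly 60/27/13% of children in the
  normal/moderate/severe categories. A direct-category mode samples the
  observed 56.4/24.1/19.5% split exactly (HAZ then drawn from matching
  truncated normals) for tests that need controlled proportions.
- `Neuro = 0.35·SES + 0.30·(HAZ+1.75) + 0.15·d + ε(0.8)`.
- Indicators are loading × latent + noise, then discretized: ASQ domains
  rounded to the 0–60 grid in steps of 5 around mean 45 (domain loadings
  1.0/1.25/0.9/1.2/0.85 weight Problem-Solving and Fine Motor most; item
  mechanics of the questionnaire are not modelled because the analysis only
  consumes domain scores); SES indicators as ordinal/binary/count variables
  cut at fixed quantiles of their continuous projections; BCAA
  concentrations in µmol/L around realistic panel means. The overall score
  is the exact sum of the five discretized domains by construction.
- Context variables (parasites at the published prevalences, food groups,
  breastfeeding, ferritin/CRP log-normals, reported birth size) are drawn
  independently of the structural core; they exist to exercise the
  screening layers, not to carry effects.
- Missingness is MCAR-only, off by default, restricted to biomarker and
  maternal-age columns, so listwise deletion can be tested without
  confounding the structural equations.

The count table emulates a 16S ASV data set: 1626 taxa in 30 families
(Streptococcaceae always present), library sizes Poisson around 22,039,
per-sample compositions Dirichlet with total concentration 300 around a
log-normal base composition. The diversity driver reshapes each sample's
expected composition by shifting every taxon's log-concentration
proportionally to its negated standardized log base abundance — a pure
evenness dial — with the vector renormalized so total concentration (hence
sampling noise) is constant. Two earlier designs (family-level shifts;
unnormalized shifts) made the sign of the Shannon–driver coupling depend on
the realized base composition; the shipped design is monotone increasing by
construction. An optional switch couples the Streptococcaceae family
negatively to the neurodevelopment latent; it is off by default, matching a
generating truth in which the microbiota acts on neurodevelopment only
through α-diversity.

What the generator does *not* emulate: read-level sequencing error,
compositional zero-inflation beyond what multinomial sampling produces,
the case–control matching design (age/sex/neighborhood/season), batch
effects beyond a random run label, and any non-linearity or
ordinal-threshold measurement process. Passing tests therefore show that
the estimators recover effects under a linear-Gaussian truth with
discretized indicators — not that they would be unbiased on the real
cohort's sampling design.

## Microbiota constructs

Alpha diversity is computed on unaggregated counts without rarefaction
(Shannon in nats, inverse Simpson, richness). The CLR transform adds a
pseudocount of +1 to counts (a depth-aware alternative can be passed via
the `pseudocount` argument). PCoA is classical scaling: double-center
−D²/2, eigendecompose, keep positive-eigenvalue axes, report
variance-explained over the positive spectrum; each axis's sign is fixed so
its largest-magnitude coordinate is positive. Ward clustering uses the
Murtagh–Legendre "Ward2" criterion (hclust's `ward.D2`: Lance–Williams on
squared dissimilarities, heights on the distance scale), delegated to
scipy's ward linkage, whose heights match `hclust(..., "ward.D2")` to
1e-6 in the test suite. The number of clusters automates the visual elbow:
the Calinski–Harabasz index — computed from pairwise distances via the
within-cluster sum-of-squares identity — is evaluated over k ∈ [2, 10] and
the chosen k maximizes its second difference with CH(1) ≡ 0, ties to the
smaller k. On two-cluster structure this selects k = 2. Taxon screening
correlates relative abundances (family or genus aggregated) with each
score by Pearson's r, BH-corrected within score; zero-variance taxa are
reported missing and excluded from the BH family size. Samples with zero
abundance in a family are retained. Quartile contrasts use
linear-interpolation quantiles (score ≤ Q1 vs ≥ Q3, middle dropped).
Bray–Curtis distances are bounded in [0,1] on compositions but are not a
metric (the triangle inequality can fail); nothing downstream assumes it.

## Regression and screening layer

OLS is solved by normal equations with classical standard errors and
t-based 95% CIs; rows with any missing value in the response or design are
dropped and the retained n reported. The Breusch–Pagan statistic is
n·R² of the auxiliary regression of squared residuals on the design,
referred to χ² with one df per regressor; its type-I error calibrates to
≈5% in the suite. The visual regression diagnostics are exposed as numeric
summaries (max |standardized residual|, max Cook's distance) instead of
plots. Adjusted stunting contrasts dummy-code the category with "normal"
as reference (order normal → moderate → severe).

The mixed-type association measure is Spearman's r (continuous pairs),
bias-uncorrected Cramér's V = √(χ²/(n·min(r−1, c−1))) (categorical pairs),
or the square root of a one-way ANOVA R² (mixed pairs, continuous as
response — invariant to which argument carries which type flag). A block
is eligible for a latent construct iff it has ≥ 4 indicators and the
*median* absolute off-diagonal association is ≥ 0.2. The 0.2 figure is the
published screening threshold; the median aggregation operationalizes what
was originally a visual inspection of correlation plots and is
configurable.

## The SEM engine

Covariance-only analysis (no mean structure). Estimation details:

- **Scaling.** One loading per latent is fixed to 1 (anchor indicator).
- **Optimizer.** BFGS on F_ML with an analytic gradient
  (dF = tr[(Σ⁻¹ − Σ⁻¹SΣ⁻¹)dΣ] with RAM derivatives reduced to four matrix
  products per evaluation), max 500 iterations, deterministic starts (free
  loadings 1, paths 0, variances half the observed variances, covariances
  0). The optimization runs on standardized data — F_ML and χ² are
  invariant under diagonal rescaling and the solution maps back to raw
  units exactly (edge parameters by scale(target)/scale(source),
  (co)variances by the scale product, latent scales tied to their anchor
  indicator) — which makes convergence behavior independent of the units
  of measurement; models containing numerically fixed (co)variances are
  fitted on the raw scale where those constants live. The analytic
  gradient replaces the finite-difference gradient an earlier design
  called for; the numerical Hessian of F_ML is kept for standard errors,
  acov = (2/(n−1))·H⁻¹. A fit is declared converged when the gradient
  ∞-norm (standardized scale) is below 1e-5 after up to two polish runs;
  non-positive-definite Σ(θ) during line search returns +∞ so the search
  backs off.
- **Defaults.** Endogenous variables get free residual variances; exogenous
  variables free variances; all pairs of exogenous variables (latent or
  observed) free covariances — the standard convention for recursive
  models with correlated inputs. Extra covariances and fixed values can be
  declared per model.
- **χ² convention.** (n−1)·F_min with S on the n−1 denominator (Wishart
  convention), used consistently in RMSEA; software packages differ here
  and the convention is stated so results are comparable.
- **Missing data.** Listwise deletion over the model's observed variables,
  retained n reported. No FIML.
- **SRMR** includes the diagonal (variance) residual cells.
- **Heywood cases** (negative residual variances) are not constrained away;
  they are flagged on the fit object.
- **df accounting.** p(p+1)/2 − #free; the shipped catalog's counts
  (50 / 51 / 168 / 9 for the four topologies with a one-column microbiota
  construct) are recorded in a fixture and verified.
- A just-identified model (df = 0) reports CFI = TLI = 1, RMSEA = 0 by
  convention.

Effect decomposition uses the full edge matrix: total = (I−A)⁻¹ − I,
direct = the A entry, indirect = total − direct (exact additivity by
construction); delta-method SEs via a numerical Jacobian of the three
effects against the estimated parameter covariance. A source with no
outgoing route to the outcome has all three effects exactly 0 and an
undefined z.

## The model catalog

Four topologies, each instantiable with any of the four microbiota
constructs (Shannon, Streptococcaceae relative abundance, first principal
coordinate, 2-group cluster label):

1. **simplest_sem** — Neuro ~ SES + HAZ + M; only direct effects.
2. **simple_sem** — adds HAZ ~ SES and M ~ SES (SES may act through
   stunting and through the microbiome).
3. **complex_sem** — adds latent BCAA, hemoglobin, binary AAT, age and
   reported birth size (coded 1/2/3): Neuro ~ SES + HAZ + M + AAT + age +
   birth size; HAZ ~ SES + hemoglobin + BCAA + M; M ~ SES + BCAA. BCAA and
   hemoglobin deliberately have no direct edge into Neuro (they were not
   associated with neurodevelopment in multivariate regressions), so their
   influence is purely mediated; the M → HAZ edge gives the microbiome its
   HAZ-mediated indirect route.
4. **complex_path** — the same shape with observed proxies only: overall
   score as the outcome; rooms and maternal age at first pregnancy for
   SES; leucine for BCAA; anemia for hemoglobin.

The exact edge set of the complex models beyond the published narrative
(e.g. BCAA → microbiota, hemoglobin → HAZ) follows the described complex-
model diagram: BCAA negatively associated with Shannon diversity,
hemoglobin acting on stunting directly and on neurodevelopment only
through it.

## Problem sizes used by the shipped checks

Simulation-based checks run at the sizes a single CPU handles comfortably
while keeping Monte-Carlo error well below the tolerances: parameter
recovery at n = 2000 with 100 replicates per topology; mediation at
n = 5000 with 200 replicates; Breusch–Pagan calibration with 1000
replicates of n = 200; the end-to-end null-mediation calibration with 100
pipeline replicates at n = 500; single end-to-end effect checks at
n = 2000. The acceptance script uses 50 recovery replicates and 100
mediation replicates per quantity for the same reasons.

## Known limitations

- Ordinal and binary indicators enter the covariance analysis as numeric;
  no polychoric correlations, so coefficients on those indicators are
  attenuated relative to a threshold model.
- No robust (sandwich) or weighted least-squares estimators; no
  multiple-group SEM; no Bayesian estimation.
- The elbow automation is a surrogate for a judgment call; on data without
  clear cluster structure the chosen k is best treated as descriptive.
- The generator's independence assumptions (e.g. birth size independent of
  HAZ) make some pipeline outputs trivially null; they are placeholders
  for structure the real cohort may well have.
- Sequencing run enters the diversity–score regressions as a covariate but
  is not included in the SEM specifications.
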