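# Methods

## Model

For individual i at time point j = 1..J the observed measurements are an
FFQ value Q_ij, a food-record value R_ij and a surrogate biomarker M_ij,
related to latent intake by

    T_ij = T_i + h_ij
    X_ij = α_Xj + β_X T_ij + γ_X' Z_Xij + ε_Xij,    X ∈ {Q, R, M},

conditional on covariate blocks Z_T (associated with true intake), Z_Q and
Z_M (associated with reporting/assay error).  T_i is the long-term average
intake with conditional variance σ²_T; h_ij are independent within-person
deviations with time-specific variances σ²_hj, independent of T_i, the
covariates and all errors.  Errors are jointly normal with mean zero and
time-specific variances σ²_Xj.  The error correlation structure is: free
correlations between repeated FFQ errors (ρ_QQ,jk), repeated record errors
(ρ_RR,jk), and FFQ-record pairs both at the same visit (ρ_QR,jj) and across
visits (ρ_QR,jk, ordered in (j,k)); zero correlation between any self-report
error and any biomarker error; and a single correlation ρ_MM shared by all
pairs of repeated biomarker errors.

Identifiability requires fixing one instrument's intake-related bias;
following standard practice the food record is chosen, but instead of
assuming β_R = 1 the pair (β_R, ρ_MM) is treated as a *sensitivity setting*:
fixed, not estimated, and swept over a grid.  Likewise the covariate effects
on the food record (γ_R) and the intake intercept (α_T, and the covariate
mean contribution to T) are not identified and are fixed at zero; they only
shift other intercepts.

Implied moments.  With slot ordering (Q_1..Q_J, R_1..R_J, M_1..M_J) the
conditional covariance is Σ = L Σ_T L' + D C D, where L carries β_X on the
matching time slot, Σ_T = σ²_T 11' + diag(σ²_h), D = diag(σ_Xj) and C is the
3J × 3J error correlation matrix described above.  Useful entries:
var(X_j|Z) = β_X²(σ²_T + σ²_hj) + σ²_Xj; cov(X_j, Y_j|Z) = β_X β_Y (σ²_T +
σ²_hj) + ρ_XY,jj σ_Xj σ_Yj; cross-visit covariances replace σ²_T + σ²_hj by
σ²_T.

Derived quantities.  The regression dilution ratio for instrument X at
visit j is cov(T, X_j|Z)/var(X_j|Z):

    λ (long-term exposure T_i)      = β_X σ²_T / var(X_j | Z)
    λ (time-specific exposure T_ij) = β_X (σ²_T + σ²_hj) / var(X_j | Z)

and corr(X_j, T | Z) follows from the same covariances.  These forms were
derived from the covariance algebra above and are verified in the test suite
against brute-force regression/correlation of simulated latent truth on
simulated measurements (10⁶ draws, agreement within Monte-Carlo error).
Since the time-specific numerator weakly dominates the long-term one, the
time-specific RDR is never smaller at fixed parameters.

Two exact invariances (both verified to optimizer precision in the tests):

- Replacing β_R by cβ_R maps the ML solution by β̂_Q → cβ̂_Q, β̂_M → cβ̂_M,
  σ̂²_T → σ̂²_T/c², σ̂²_h → σ̂²_h/c², leaving error variances and
  correlations untouched, dividing every RDR by c and leaving every
  correlation with truth unchanged.  β_R is therefore a pure relabelling of
  the latent scale; only quantities tied to the record's own scale move.
- Changing ρ_MM can be absorbed by adjusting β_M, σ²_T, σ²_h, the error
  variances and the self-report error correlations while the implied Σ (and
  hence β̂_Q, which is pinned by the ratio of FFQ-biomarker to
  record-biomarker cross-covariances) stays fixed.

Back-transformation.  When the model holds on the log scale but the
outcome model uses untransformed intake, the original-scale RDR is computed
by Monte Carlo: simulate the bivariate normal (T, X_j) implied by the fit,
exponentiate both coordinates and take the slope cov(e^T, e^X)/var(e^X).
This choice (rather than a closed lognormal formula) keeps the estimator
correct for any exposure definition and any fitted intercepts; the classical
special case has a closed form via the bivariate normal moment generating
function, which the tests use as an independent oracle.  The estimator is
seed-reproducible and requires at least 10⁴ draws.

## Fitting

Full-cohort maximum likelihood.  Individuals are grouped by their
observed-slot pattern; each pattern contributes the marginal normal log
density of its observed subvector, evaluated from pattern-level sufficient
statistics (count, mean, scatter), which makes the likelihood cost
independent of n after one pass.  The summed value equals the
individual-level sum to numerical precision, and the fit uses every
individual with at least one observed measurement — valid and efficient when
data are missing at random.

Covariates are handled in two steps: each measurement column is replaced by
residuals from an OLS regression on (Z_X, Z_T) fitted per slot, the
covariance structure is estimated on the residuals with means fixed at zero,
and covariate effects are then recovered: γ_T from a random-intercept mixed
regression of R_ij on Z_T divided by β_R (the record carries no covariate
effects of its own); γ_Q and γ_M from mixed regressions of the constructed
responses Q_ij − (β̂_Q/β_R)R_ij on Z_Q and M_ij − (β̂_M/β_R)R_ij on Z_M,
which strip the intake signal.  Mixed models are fitted by ML (not REML) for
consistency with the main likelihood, random intercept only; when the
random-effect structure is degenerate (no repeats, singular variance) the
code falls back to ordinary regression with a logged warning.  Standard
errors of γ̂_Q and γ̂_M ignore the uncertainty in the plugged-in scalings.

Caveat on residualization under MAR: demeaning uses per-column observed-row
means, which is only correct when missingness is unrelated to the values
(MCAR) or covariate-explained.  For data with informative (MAR) missingness
the fit should run on non-residualized data with `free_intercepts=True`, so
the intercepts are estimated jointly inside the likelihood; this is what the
MAR tests and the acceptance script do.

Parameterization and optimizer.  Variances enter the optimizer as logs and
correlations via atanh, so box constraints are unnecessary; joint positive
definiteness of Σ is enforced by returning a large-penalty sentinel whenever
the Cholesky factorization fails (elementwise bounds cannot guarantee joint
PD).  Optimization is L-BFGS-B with three-point finite-difference gradients,
relative function tolerance 1e−13 and gradient tolerance 1e−8, restarted
from its own solution up to three times (a restart clears the quasi-Newton
history and escapes premature flat-progress termination); optional jittered
multistarts guard against local optima, which become a real concern at high
ρ_MM.  A failed line search at an already-stationary point (typical when a
fit is warm-started at an exact solution) is accepted as convergence when
the relative gradient is at finite-difference noise level (below 1e−6).  Starting values are moment-based: the pairwise-complete sample
covariance is pushed through the model equations where invertible
(cross-instrument cross-visit covariances isolate β_M σ²_T etc.), with
neutral fallbacks (β = 1, correlations 0.3, half-variance splits) wherever
the data cannot support the inversion, and correlation shrinkage until the
error block is positive definite.  With J = 1 the within-person variance is
indistinguishable from σ²_T and is fixed at zero automatically.

Standard errors.  Delta method by default: the observed information is the
numerically differenced Hessian of the negative log likelihood at the
optimum (transformed scale); its inverse is propagated through the
natural-parameter and derived-quantity maps by central-difference Jacobians.
A nonparametric bootstrap (resampling individuals, refitting from the point
estimate, seed-reproducible) is available and is the automatic fallback when
the information matrix is singular.  Quantities fixed by the sensitivity
setting are reported with standard error exactly zero.  The two methods
agree within sampling noise in the tests.

Identifiability accounting.  `dof_check` counts free covariance parameters
against distinct observed second moments for a given design (which
instrument-visit slots exist) and constraint preset.  σ²_hj is counted as
free only when at least two visits are observed overall and at least two
instrument types at visit j.  The check is combinatorial — a necessary, not
sufficient, condition — and says so in its report.  With all six slots at
J = 2 the full model has 17 free parameters against 21 moments; with three
slots at J = 1 the same-visit FFQ-record error correlation must be fixed to
reach a just-identified 6-against-6 configuration.

## Sensitivity analysis

`run_grid` refits the model at every (β_R, ρ_MM) cell on the identical
preprocessed dataset.  Within a ρ_MM column, later β_R cells are
warm-started from the column's first solution pushed through the exact β_R
rescaling map, which costs almost nothing and is start-independent because
the map is exact; each new ρ_MM column starts from fresh moment-based
values.  Cell failures are recorded with their diagnostic and rendered as
"NC" in the summary tables rather than dropped.  Subset (stratified)
analyses are row filters applied before the sweep — no special code.  No
automatic selection of a "most plausible" cell is attempted; that judgement
is scientific, not algorithmic.

## Synthetic data generator

`gen_dataset` draws exactly the model's stochastic structure: covariate
blocks (binary/normal/categorical columns, optionally redrawn per visit),
T_i normal around γ_T'Z̄_i, independent h_ij, and a 3J-dimensional error
vector with the full correlation structure including ρ_MM and the
self-report/biomarker zeros.  Self-reports are produced on the log
(analysis) scale — real intake data are approximately normal after log
transformation — and the biomarker on its natural scale; `to_raw_scale`
exponentiates the self-reports for end-to-end pipeline exercises.
Missingness is overlaid as MCAR (independent per-slot deletion) or MAR
(deletion probability a logistic function of an always-observed driver
slot); raw-scale artifacts add reported zero intakes and high biomarker
outliers.  A single master seed expands into independent substreams
(covariates, truth, errors, missingness, artifacts) so components vary
independently.  The latent truth table is returned separately and never
leaks into the dataset.

The reference scenario (`fruit_veg_scenario_params`) is a two-visit cohort
with β_Q = 0.66, β_M = 50 biomarker-units per log-intake-unit, σ²_T = 0.07,
σ²_h = (0.014, 0.009), self-report error variances 0.25–0.41, biomarker
error variances 117 and 181, and self-report error correlations 0.38–0.65 —
magnitudes representative of a large fruit-and-vegetable validation study
with a plasma-vitamin-C-type biomarker.  What the generator deliberately
does not emulate: non-normality and skew of real intake on the analysis
scale, covariate-dependent error variances, seasonal/calendar structure,
correlated within-person deviations across visits, or supplement-use
contamination beyond a crude additive outlier.  Tests passing on this
generator therefore demonstrate internal correctness of the estimator and
derivations, not robustness to those real-data departures.

## Preprocessing rules

On raw-scale input: values ≤ 0 in log-transformed instruments are set
missing before the log (reported zero intakes are treated as missing rather
than as true zeros); biomarker values strictly above Q3 + 2·IQR — quantiles
by linear interpolation between order statistics, computed per visit over
non-missing values, before transformation, biomarker only — are set missing
as likely supplement users.  Both the quantile convention and the per-visit
application are config-visible choices and are recorded in the run log along
with exclusion counts.  Preprocessing marks the dataset as analysis-scale
and is idempotent.

## Numerical choices and degenerate inputs

- Non-PD implied covariance during optimization → finite large penalty;
  in the public `loglik` → −∞, never an exception.
- σ²_h = 0 is allowed (time-constant truth); the log transform keeps the
  optimizer strictly positive but arbitrarily small.
- Zero scaling (β_X = 0) or zero variance makes RDR/correlation requests
  raise a degenerate-instrument error rather than return nonsense.
- Rank-deficient covariate designs are rejected with the collinear columns
  named.
- Statistical test calibration: several suite checks compare hundreds of
  Monte-Carlo z statistics against a 3-standard-error band; they allow the
  band's own nominal exceedance rate (≤1% of entries, hard cap 4 SE)
  rather than demanding a simultaneous bound that a correct implementation
  would fail by chance.

## Problem sizes

Unit tests simulate 10³–3·10⁵ individuals; oracle comparisons use 10⁶;
parameter-recovery and invariance checks fit n = 20000 cohorts (each fit
takes on the order of a second thanks to pattern-level sufficient
statistics), with 20 replicates for interval-coverage calibration.  The
acceptance script uses n = 10⁶ for moment verification and n = 20000 for
all fitting.

## Known limitations

- No estimating-equations / method-of-moments fitting; no REML; no
  multivariate (multi-nutrient) extension; no outcome-model fitting — RDRs
  are exported for downstream calibration only.
- No person-specific/random error split: errors are modelled as combined
  terms with free correlations, which is more flexible across visits but
  cannot attribute error to stable individual reporting styles.
- Mixed-model γ standard errors ignore uncertainty in β̂_Q, β̂_M.
- The delta method relies on a well-conditioned observed information;
  heavily constrained or near-degenerate fits should use the bootstrap.
- ρ_MM is a single scalar for all visit pairs; with J > 2 a per-pair
  generalization might be wanted but is intentionally not offered.
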