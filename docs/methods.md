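# Methods

## Model

A placental epigenetic clock is a sparse linear predictor of gestational
age: for a vector of beta values x (methylation fractions in [0, 1] at the
clock's CpGs), predicted GA in weeks is β₀ + xᵀβ. Coefficients are
estimated by elastic-net regression,

    (1/2n) Σᵢ (yᵢ − β₀ − xᵢᵀβ)² + λ (α‖β‖₁ + (1−α)/2 ‖β‖₂²),

with mixing parameter α = 0.5 by default and the shrinkage λ selected as
the minimizer of mean cross-validated MSE over a descending path of 100
log-spaced values from λ_max (the smallest λ at which all coefficients are
zero) down to 10⁻⁴·λ_max. Folds (default 10) are assigned by a seeded
partition stratified by GA quartile; stratification stabilises the CV
curve at the sample sizes we target. Predictors are standardized
internally during fitting and coefficients are transformed back to the
raw beta scale, so a trained model is an ordinary coefficient table and
`predict_ga` applies any such table, including published ones. The
optimizer is scikit-learn's coordinate descent, whose penalty
parameterisation matches the objective above (for the logistic sex
classifier, C = 1/(nλ)).

Assumptions: GA-associated methylation drift is approximately linear in
beta over the gestational range; betas are already normalized (array
normalization, IDAT handling and batch correction are out of scope); GA
itself is measured without the clock (ultrasound/LMP dating).

Training variants are filters, not different estimators: the robust
recipe uses all samples including complicated pregnancies (so selection
cannot lean on condition-correlated CpGs), the control recipe restricts
to condition == "control", and the refined recipe restricts to
uncomplicated term samples (control and GA > 36 weeks) *and* to the
parent clock's CpGs, which guarantees the refined feature set is nested
in the parent's.

## QC

The outlier rule is a three-step recipe: (1) gold standard = per-probe
median beta across all samples (even-count median = mean of the two
central values); (2) Pearson correlation of each sample against the gold
standard over pairwise-complete probes; (3) exclude samples with r < 0.9.
The gold standard is computed once from all samples, prospective outliers
included — it is not recomputed iteratively. A zero-variance sample
profile has undefined r and is excluded with an explicit reason. Missing
cells are imputed with the gold-standard medians; the operation is a pure
transform and the caller decides its scope (the training pipeline imputes
training data only). Duplicate handling is exact-identifier
deduplication; correlation-based replicate detection is not attempted.

## GA acceleration

Acceleration is the raw residual of OLS of predicted on observed GA
(slope and intercept reported). Least-squares orthogonality makes the
residual uncorrelated with observed GA (tests assert |r| < 1e-10), so
group comparisons are not confounded by the groups' GA distributions. A
standardized variant divides by the residual SD. Raw residuals are the
default; the standardized form is an option for cross-cohort display.

## Stratified EWAS

Within each stratum the association between a CpG and GA is the biweight
midcorrelation: with m = median(x) and d = median(|x − m|), u = (x − m)/(9d),
weights a = (1 − u²)²·1[|u| < 1], and transformed values x̃ = (x − m)a, the
correlation of x̃ and ỹ. If d = 0 the transform is undefined and the
implementation falls back to Pearson for that vector; no outlier-fraction
cap is applied (a deliberate simplification of the screening convention).
The correlation is mapped to t = r√((n−2)/(1−r²)), a two-sided Student-t
p-value, and a sign-preserving normal Z via the log-scale quantile, so
each stratum's (z, p) pair is self-consistent deep into the tail; |r| = 1
yields the machine-minimum p with Z capped at ±40. Strata are combined as
Z_meta = Σ Zᵢ√nᵢ / √Σnᵢ (weights √nᵢ, invariant to rescaling all nᵢ) and
the meta p-value is 2(1 − Φ(|Z_meta|)) evaluated through the log survival
function (|Z| ≈ 10 → ~1e-24; values below the subnormal floor report the
smallest positive double rather than 0). Significance is a fixed
genome-wide threshold, default 1e-7, with no further correction. Probes
with missing values use pairwise-complete observations and record their
effective n.

## Evaluation

Accuracy is the median absolute error (weeks) and Pearson r between
predicted and observed GA. The MAE interval is a percentile bootstrap
(B = 1000, seeded) over paired resamples; the r interval is the Fisher-z
approximation. Neither interval is intended to match any externally
printed interval — the CI method behind published values is not specified,
so ours is simply documented. Standard subgroups: all samples, GA > 25
weeks, uncomplicated term.

## Simulator

`simulate_dataset` draws GA uniformly over a configurable range (default
6–42 weeks, the span of public placental cohorts); condition assignment
precedes the GA draw so a condition's GA shift models earlier delivery.
Clock CpGs have mean μⱼ(GA) = clip(aⱼ + bⱼ·GA, 0.02, 0.98) with baselines
aⱼ ~ U(0.1, 0.9) and slopes bⱼ of random sign and magnitude U(0.005, 0.02)
beta units/week by default; observed betas are Beta(μφ, (1−μ)φ) with
precision φ = 50, chosen so the per-probe noise SD (~0.07 at μ = 0.5)
resembles inter-sample variability on normalized arrays while keeping
values in [0, 1] with one knob. Sex CpGs shift by 0.2 in males; condition
CpGs shift by the configured amount in affected samples; outlier samples
are replaced by i.i.d. U(0, 1) betas; missingness is uniform. Everything
is reproducible from the config seed.

What the simulator does *not* emulate: probe-type chemistry differences,
batch structure, cell-composition variation, bimodal/imprinted probes,
copy-number (trisomy) dosage, and correlated probe blocks. Passing tests
therefore demonstrate correctness of the statistical machinery under the
assumed generative model, not expected accuracy on real arrays.

Preset scenarios fix the study conditions used by the tests:
`clock_recovery` (400×2,000, 50 clock CpGs), `ewas_twostrata` (831 control
+ 70 preeclampsia — the stratum sizes of the motivating EWAS — GA 28–42
weeks with a −6-week shift and +0.15 beta shift at 50 condition CpGs, a
confounding magnitude large enough to be unmistakable yet within the
plausible range for a strong pregnancy condition), `sex_sep` (300×2,000,
50 sex CpGs at +0.2) and `qc_outliers` (96 clean + 4 planted outliers over
5,000 probes). These sizes keep every analysis at desk scale (seconds to
~1 minute each) while leaving enough samples per fold and stratum for the
statistics to behave asymptotically.

## Numerical choices and degenerate inputs

* Fixed-λ fits converge to tol ≤ 1e-8 so the λ→0 limit reproduces OLS to
  1e-6; CV path fits use tol 1e-4.
* λ_max uses max(α, 1e-3) in its denominator so the ridge limit (α = 0)
  keeps a finite path. The logistic path stops at 10⁻²·λ_max: on
  separable data the weakly regularized tail is never selected and
  dominates solver time.
* Clock files round-trip bit-exactly: floats are written with `repr` and
  parsed with pandas' round-trip parser.
* Sex prediction at probability exactly 0.5 returns the negative class
  (deterministic tie-break).
* Beta values exactly 0 or 1 are accepted unchanged; no smoothing is
  applied anywhere.
* Empty probe intersections warn rather than raise; all-missing probes
  get a missing gold-standard median and block imputation with an error
  naming them.

## Known limitations

* Accuracy claims transfer to real arrays only insofar as the generative
  model holds; the simulator's independence across probes flatters
  feature selection.
* The EWAS omits genomic-inflation control and cell-type adjustment by
  design (out of scope).
* Published per-stratum Z/p tables rounded to one decimal are not exactly
  reproducible under any single z↔p convention; the package asserts only
  self-consistent identities (meta-Z arithmetic and the z↔p mapping), not
  every printed cell.
* Foreign clocks are supported purely as coefficient tables; nonlinear
  age transforms used by some adult clocks are not implemented.
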