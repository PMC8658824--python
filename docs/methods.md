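# Methods

This note records the model, the numerical conventions and the open design
choices behind `thermoramp`, in enough detail that a maintainer can judge
what a passing test suite does and does not demonstrate.

## Model and assumptions

The analysis assumes single-substrate Michaelis–Menten steady-state kinetics
with a temperature-dependent turnover number obeying the Arrhenius law,

v(T, S) = kcat(T)·E0·S/(KM + S),  kcat(T) = A·exp(−Ea/(R·T)),

over a temperature range in which the enzyme stays folded and active, KM is
effectively constant, and E0 is unchanged (no aggregation, no interfacial
activation, no product inhibition). The gradient experiment further assumes
the ramp is slow enough that the cuvette contents equilibrate with the block
temperature and that, within one rolling window, the reactant-stationary
approximation holds.

Transition-state conversion uses the Eyring equation with transmission
coefficient κ = 1: ΔG‡ = R·T·ln(kB·T/(h·kcat)). ΔH‡ = Ea − R·T (solution
reaction, one quasi-thermodynamic degree of freedom exchanged), and
TΔS‡ = ΔH‡ − ΔG‡ by definition; both identities hold exactly in the output
by construction. R is carried in kcal (1.9872×10⁻³ kcal·mol⁻¹·K⁻¹) so every
energy is reported in kcal/mol.

## Pipeline parameters

| parameter | default | meaning / rationale |
|---|---|---|
| window | 4 readings | rolling-OLS span per cuvette; small enough that the temperature-driven velocity change within one window is minor at 1–2 K/min with one reading per kelvin. Stride is 1, so the terminal temperatures lose (window−1) points. |
| n_bins | 10 | equal-width temperature bins over the observed range; more bins → less within-bin temperature variation but fewer points per fit. Chosen so a 21 K ramp gives ~2 K bins with ~20 velocity points each under the default design. |
| min_points_per_bin | 4 | bins below this are skipped with a warning; a two-parameter fit on fewer points is meaningless. |
| temperature cut-offs | none | researcher-controlled interval filter to drop bins where the enzyme is inactivating; non-converged or non-physical (kcat ≤ 0, KM ≤ 0) bin fits are always excluded. |
| weights | 1/SE(kcat)² | applied to the ln kcat regression. This is deliberately the convention of the original tooling even though the regressand is logarithmic; the first-order-consistent alternative (kcat/SE)² is available as `weight_scheme="delta-log"`. |
| T_ref | mean binned temperature | Ea is T_ref-independent; ΔG‡/ΔH‡/TΔS‡ shift smoothly (∂ΔH‡/∂T_ref = −R). |

Window temperature and substrate are arithmetic means over the window — the
slope is a window-average rate, so its natural covariates are window
averages. Out-of-range product concentrations (noise driving P below 0 or
above S0) are flagged, never dropped; exclusion happens only through the
explicit cut-offs.

Standard errors: Michaelis–Menten fits use the residual-variance-scaled
inverse Jacobian normal matrix (the usual linearised covariance from
Levenberg–Marquardt); the Arrhenius stage uses the weighted-least-squares
parameter covariance with residual variance scaling; activation-parameter
errors follow by the delta method (the ΔG‡ error is R·T_ref times the
standard error of the fitted mean ln kcat at 1/T_ref). Confidence intervals
use Student's t with n−2 degrees of freedom.

## Model comparison

AICc = n·ln(RSS/n) + 2k + 2k(k+1)/(n−k−1), computed on the weighted
ln kcat-scale residuals with the same weights as the Arrhenius fit, and with
the residual variance counted as a parameter (k = coefficients + 1) to match
common graphing software. Two comparison modes exist: the default *nested*
mode (one pooled line, k = 3, vs independent per-dataset lines, k = 2d+1,
both scored on all n points) and a *three-way* mode (the pooled line vs each
dataset's own line on its own points), which mirrors how such comparisons
are often reported. AICc magnitudes depend on these conventions; orderings
and Akaike weights are the meaningful output.

## Simulator

`simulate_ramp` integrates dS/dt = −kcat(T(t))·E0·S/(KM+S) per cuvette with
a fixed-step classical RK4 scheme (step ≤ 1 s, sub-stepping so samples land
exactly on reading times). Fixed step was chosen over adaptive integration
for bit-reproducibility across platforms; at these rates the RK4 error is
orders below the 10⁻⁶ relative tolerance the closed-form progress-curve test
demands, and a guard raises if any step would consume more than 20% of the
remaining substrate. Cuvettes are read round-robin with a dead-time offset
emulating a multi-position sample changer.

Default conditions mirror a cold-active lipase assay: Ea = 15.325 kcal/mol
(slope −7712 K), ln A = 32.06, KM = 200 µM, E0 = 1 nM, a six-step 1:1
dilution series from 1 mM measured in duplicate (12 traces), 277.15→298.15 K
at 2 K/min, one reading per cuvette per 1 K of ramp, ε = 17,800 M⁻¹cm⁻¹,
1 cm path. Twelve traces rather than six matters: with a single dilution
series the interaction between the sample-changer schedule and the bin edges
leaves each bin's Michaelis–Menten fit confounded by within-bin temperature
spread, producing erratic percent-level Ea biases; the duplicate series — the
design the gradient experiment actually uses — averages this out (zero-noise
closure error ≈ 0.7%).

Noise is additive Gaussian on absorbance (instrument-side), seeded; "1%
noise" in the validation means sd = 0.01 AU against a 1 AU full-scale
reading. KM is temperature-constant by default; an optional van 't Hoff
enthalpy (`km_van_t_hoff`) adds KM(T) for robustness studies only.

What the simulator does **not** emulate: enzyme inactivation/unfolding at
the hot end, substrate or product inhibition, interfacial activation, buffer
pKa drift with temperature, photometric non-linearity, or drift/1-f noise.
Passing closure tests therefore show the estimator is unbiased under the
model's own assumptions at realistic noise — not that those assumptions hold
for any particular real enzyme; the temperature cut-offs exist precisely
because real data violate them at the range ends.

## Numerical conventions and degenerate inputs

* Rolling slopes use the centred two-pass OLS formula (exactly shift
  invariant; validated against an independent oracle to 1e−12 relative).
* Temperature auto-detection treats values < 150 as Celsius — no assay runs
  below 150 K — making unit normalisation idempotent.
* Michaelis–Menten initial guess: kcat₀ = max(v)/E0, KM₀ = median(S).
  Non-convergence and non-physical optima are flagged and excluded, not
  clamped, so a pathological bin cannot drag the Arrhenius line.
* Binning is equal-width with an inclusive upper edge; empty bins are
  dropped with a notice. A degenerate all-one-temperature point set widens
  to a single ±0.5 K bin rather than failing.
* A two-point Arrhenius "fit" interpolates exactly with undefined (NaN)
  covariance; three points is the enforced minimum downstream.
* JSON outputs are serialised with sorted keys and default float repr, so
  identical inputs reproduce byte-identical result files.

## Validation scale

The test suite validates the pipeline closure at the default experiment
size (12 traces × 21 readings): a zero-noise ramp recovers Ea within 2%,
and across 200 seeded replicates at 0.01 AU noise the median Ea error stays
under 5% — the package's simulated-data validation claim. The full suite
runs in well under a minute on one CPU.

## Known limitations

* Weighting by 1/SE(kcat)² on a log-scale regressand over-weights large
  kcat bins; use `delta-log` when statistical efficiency matters more than
  matching the published convention.
* Per-bin independent fits discard cross-bin smoothness; global fitting of
  (Ea, A, KM) directly to all velocities would be more efficient but is out
  of scope here.
* AICc magnitudes are convention-dependent (weighting, k counting); only
  compare values produced by this package with each other.
* No curved-Arrhenius (ΔCp‡ ≠ 0) model: enzymes with strongly curved plots
  will show it as systematic residuals, not as a fitted heat capacity.
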