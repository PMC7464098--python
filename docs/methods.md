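# Methods

## Scope

The package analyses two kinds of measurement on the CPR / heme–HO-1
electron-transfer pair: sedimentation-equilibrium radial absorbance scans
of the two-protein mixture (binding affinity), and UV–visible absorbance
time courses (heme-reduction kinetics and HO turnover). Because no raw
instrument data are bundled, a first-class synthetic-data module generates
every input with known ground truth; all recovery claims below refer to
those synthetic conditions.

## Sedimentation-equilibrium model

Each ideal species contributes `A_i(r0)·exp(M_i·H_i·(r² − r0²))` with
`H = (1 − v̄ρ)ω²/2RT`. The 1:1 complex term has the summed buoyant-mass
exponent and reference amplitude `K·A_HO1(r0)·A_CPR(r0)`, where `K` is the
association constant on the absorbance scale; a small radially constant
offset δ absorbs baseline error. Setting `K = 0` reduces the model exactly
to two independent monomers. The model assumes thermodynamic ideality, a
single 1:1 stoichiometry, no self-association, and radially uniform
extinction; mass conservation over the sector-shaped cell is deliberately
not imposed (see the synthetic generator below).

Unit policy: inputs are accepted in instrument conventions (rpm, cm, g/mL,
mL/g, g/mol); `H` is computed in SI with R = 8.314462618 J mol⁻¹ K⁻¹ and
reported in cm⁻² per g/mol so exponents are dimensionless with radii in
cm. Exponents whose magnitude would exceed 50 raise a diagnostic error
naming the offending radius — beyond that the model is numerically
meaningless and indicates wrong masses, speed or window.

`Kd = (ε1 + ε2)/(ε1·ε2·l)·(1/K)` converts K to molar units. `K = 0` maps
to an infinite Kd, reported explicitly as "no detectable association"
rather than as an overflow.

## Fitting

Free parameters are the two reference amplitudes, K (complex model only)
and δ. Amplitudes and K are optimised on the log scale: positivity is then
structural, and K spans three orders of magnitude across the studied
regimes (sub-μM to >100 μM Kd). δ is unbounded. Molar masses are fixed
inputs, never floated. The trust-region-reflective least-squares solver
(analytic Jacobian) is restarted from 8 seeded draws — amplitudes around
the observed absorbance at r0 split by a uniform fraction, K log-uniform
in 10⁻²–10² AU⁻¹ — because the three-exponential mixture has local minima.
Convergence uses relative-objective and step tolerances of 1e-10 with at
most 2000 evaluations per start; the best start wins, and a fit that
exhausts every start is flagged `converged = False` rather than silently
returned. Fits are deterministic given the seed and invariant to the point
order of the scan (profiles sort on construction).

The parameter covariance is `s²(JᵀJ)⁻¹` on the estimated (log) scale. The
Kd standard error follows by the delta method, `SE(Kd) = Kd·SE(log K)`;
alternatively a residual bootstrap (seeded, default 500 resamples, refit
from the point estimate) reports the SD of the refitted Kd. A singular
normal matrix falls back from delta to bootstrap with a logged warning.
Whether a reported ± is a fit SE or a replicate SD is an open convention
in the field; both routes are exposed and labelled, neither is asserted to
be canonical. A fitted K below 10⁻⁶ AU⁻¹ is treated as the no-association
boundary and propagates an infinite Kd.

## Model comparison

The monomer-only model is nested in the complex model (one parameter).
The comparison reports the RMSD ratio, the F statistic
`(SSR_nc − SSR_c)/(SSR_c/(n − 4))` with (1, n − 4) degrees of freedom and
its p-value, and Wald–Wolfowitz runs tests on the residual signs of both
fits (a mis-specified monomer model leaves long sign-correlated residual
waves). The complex model is preferred iff the F-test p-value is below α
(default 0.05); ties go to the simpler model. Because the alternative sits
on the boundary K ≥ 0, the F-test is conservative under the null, which
the type-I acceptance test confirms empirically.

## Kinetics

Initial rates come from the early window of an absorbance trace: the
earliest points covering 10% of the total excursion (end-averaged over the
last five points to tame plateau noise), minimum 5 points, or a fixed time
window when configured. Two slope estimators are provided. The default for
the Soret channels is the *tangent*: a local quadratic fit evaluated at
the window start. For a linear trace it equals the OLS slope exactly; for
exponential approach with observed rate k over a window of duration T the
plain OLS *secant* underestimates the initial slope by ≈ kT/2 (≈ 5% at a
10% excursion window), which the tangent reduces to O((kT)²). The secant
remains first-class (`method="secant"`) and is the default for the
bilirubin assay, whose early phase is linear so the secant is unbiased and
lower-variance.

Slopes convert to μM min⁻¹ through the channel's (difference) extinction
coefficient and the cuvette path length (1 cm unless configured — standard
spectrophotometer geometry). Rates are reported positive in the expected
direction (406 nm falling, 420 nm rising, 468 nm rising); for the Soret
pair both channel rates and their mean are returned, since no averaging
convention is canonical when they disagree.

The apparent reduction rate constant is the least-squares slope of initial
rate against reductase concentration (both in μM), free intercept by
default with through-origin as an option ("slope of the fitted line" does
not fix the intercept; both modes are first-class). A single distinct
concentration is an error that points at through-origin mode. HO turnover
divides the 468 nm rate by ε_bilirubin(468) and the enzyme concentration.
ε_bilirubin(468) has no bundled default — published values vary with the
assay medium — so it is mandatory configuration; the demo uses
43.5 mM⁻¹cm⁻¹.

## Synthetic data

The equilibrium generator imposes 1:1 mass action *at the reference
radius*: free concentrations from the stable positive root of the binding
quadratic, reference amplitudes via ε455 and the path length, K from the
molar Kd, then the forward model on the radial grid plus i.i.d. Gaussian
noise (σ = 0.005 AU by default, typical absorbance-optics scan noise).
Radial redistribution of the loading totals in a sector cell is *not*
modelled; since the fit targets the same model family this is
self-consistent, but it means the generator does not emulate meniscus
depletion, optical artifacts or concentration-dependent nonideality, and
passing recovery tests demonstrate estimator correctness, not robustness
to those real-data effects. Scans whose predicted absorbance exceeds a
linearity cap (default 1.5 AU) carry a warning flag, mirroring the finite
linear range of real absorbance optics.

Geometry defaults: 15,000 rpm, 25 °C, solvent density 1.004 g/mL (0.1 M
potassium phosphate), 12 mm path, radial grid 6.90–7.20 cm at 0.001 cm
steps (301 points). A 120 μL sample in a 12 mm double-sector centerpiece
forms a ≈ 0.3 cm solution column, hence the 0.3 cm window near the cell
base; r0 defaults to the window midpoint, which keeps the amplitude
parameters well-scaled. The bundled reference species carry the published
ε455 values (15.1 / 24.0 / 23.8 / 23.7 / 23.8 mM⁻¹cm⁻¹) but synthetic
nominal masses (30 kDa for heme–rHO-1; 70 kDa for the soluble CPR forms,
0.4 kDa less for the hinge-deletion mutant) and v̄ = 0.73 mL/g, because
the real constructs' exact masses and v̄ are experiment-specific inputs,
not package constants.

Reduction traces are exponential per channel, `k_obs = k_app·[CPR]/[heme]`
(pseudo-first-order in the 4.3 μM heme pool), amplitudes tied by
Δε420/Δε406 = 131/82.2, with 5% multiplicative scatter on k_obs (run-to-run
initial-rate noise) and small per-point read noise (0.001 AU). Assay traces
rise linearly until the substrate pool (default 40 μM heme) is exhausted.
All generators are pure functions of (truth, seed); per-trace child seeds
derive from the parent by fixed tags, so outputs are reproducible
element-wise across runs and platforms.

## Summary table

Percent-of-control is `100·value/control` with first-order error
propagation (relative variances in quadrature); the control row is 100 by
definition. Fold change is `control/value`. Full precision is kept
internally; rendering rounds half-even to 3 significant figures (percents)
and 2 (folds). Undetermined cells render as ND and never enter
arithmetic. The propagated percent uncertainties are reported as such and
not asserted to match any particular published convention.

## Problem sizes and determinism

Recovery studies use 25–50 seeded scans per equilibrium regime (50 for
the reported medians, where the per-fit Kd scatter at the tight-binding
regime makes the extra replication worthwhile), 200
replicates for the type-I calibration, and 50 seed replicates of the
three-concentration kinetics series — sizes at which the Monte-Carlo
error of the reported medians/means is well inside the tolerances they
are checked against. Every stochastic step draws from
`numpy.random.default_rng` seeded from explicit arguments; there is no
hidden global random state.

## Known limitations

* Single-scan fits only: no global multi-speed or multi-concentration
  analysis, no floating masses, no self-association or 2:1 models.
* The synthetic generator's idealisations listed above.
* The runs test uses the normal approximation, adequate for the ≥ 100
  point scans targeted here but approximate for very short profiles.
* Bootstrap refits start from the point estimate (2 restarts), trading
  exhaustive multi-start for speed; for pathological fits the delta
  method and bootstrap can disagree, which is surfaced, not hidden.
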