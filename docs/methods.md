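# Methods

This note records the models, assumptions, parameter choices, and
numerical decisions behind `shiftbind`, in the spirit of a package
methods appendix. Units throughout: concentrations in μM, chemical
shifts in ppm, times in s, rates in s⁻¹, energies in kcal/mol.

## CSP analysis

The combined perturbation Δ = √(Δδ_H² + (0.152·Δδ_N)²) uses the
conventional 0.152 scaling that maps the ¹⁵N shift range onto the ¹H ppm
scale. The constant is fixed (an expert override exists on
`compute_csp`/`csp_profile`, but results are then no longer comparable
with the defaults). Δ is a magnitude: sign information per dimension is
deliberately discarded at this stage.

Residue selection for binding curves requires (i) Δ strictly greater
than the profile mean, (ii) fast exchange, (iii) a resolved cross-peak.
Two choices were genuinely open and are fixed as follows: "exceeds the
mean" is a strict inequality (ties excluded), and the mean is computed
over resolved residues only, because overlapped peaks carry
untrustworthy displacements. Both choices are recorded in exported
metadata.

## Equilibrium models

Both isotherms model ligand depletion exactly; the free ≈ total
approximation is never used because the experiments run at protein
concentrations (≈100 μM) comparable to the dissociation constants.

For two independent sites the free-ligand concentration is the physical
root of the cubic mass balance
L₀ = [L] + P₀[L]/(K_d,W+[L]) + P₀[L]/(K_d,I+[L]). It is evaluated by the
trigonometric (Viète) closed form and then refined by a safeguarded
Newton iteration on the monotone mass-balance residual. The refinement
matters: the cos-term cancellation in the closed form loses up to ~10⁻³
relative accuracy when [L] is many orders of magnitude below the
coefficient scale (very large P₀, or one K_d far above the other); the
polished root agrees with a brute-force bisection oracle to better than
10⁻¹² relative across a 10⁴-point grid spanning 10⁻³–10⁶ μM per axis.
The arccos argument is clamped to [−1, 1] only within 10⁻⁹ of the
boundary — larger violations raise, since silently clamping them would
hide coefficient bugs. A degenerate discriminant (unreachable for
physical positive inputs) falls back to bisection with a logged warning.

The bisection oracle itself converges to 10⁻¹⁰ μM absolute by default;
callers who need tiny roots certified relatively can tighten `xtol`/`rtol`.

## Global fitting

All curves of an experiment are fitted simultaneously: dissociation
constants are shared, each curve owns one saturation amplitude.
Numerical design:

- K_d parameters are optimized as log₁₀(K_d/μM), enforcing positivity
  and giving near-quadratic behaviour across decades; amplitudes are
  linear and may be negative (per-dimension shifts have direction).
- Amplitudes are profiled out analytically at every objective evaluation
  (variable projection), so the nonlinear search is 1- or 2-dimensional.
  This makes the multi-start protocol cheap: 7 starts over
  log₁₀K_d ∈ {−1…5} for single-site, the 7×7 grid for two-site. The
  reported `n_starts_agreeing` counts starts landing within 1% of the
  best K_d.
- Solver: scipy trust-region reflective least squares, gradient
  tolerance 10⁻¹⁰, ≤5000 evaluations per start.
- Weighting: the objective is unweighted, but two-site ¹⁵N curves are
  placed on the ¹H ppm scale (×0.152 — the same constant as the combined
  CSP) before entering the fit. The generator's noise model (and real
  spectra) put ~1/0.152 larger position noise on the ¹⁵N axis; without
  the rescaling the noisier ¹⁵N residuals dominate the sum and K_d
  recovery at the reference noise level degrades from ~5% to ~18% median
  error. Each curve still enters individually, and its amplitude is
  reported on that scale.
- Single-site fits operate on combined-Δ curves; two-site fits on
  per-dimension curves routed to the WW- or PPIase-site occupancy by the
  residue's domain label. Linker residues have no site model and are
  dropped with a warning.
- A selection confined to one domain leaves the other site's constant
  unconstrained; it is flagged `unidentifiable` and held at its starting
  value rather than silently fitted. Fitted K_d pairs within 10% of each
  other trigger an identifiability warning.

### Uncertainty

`asymptotic` standard errors come from the numeric Jacobian of the full
parameter vector (log-K_d plus amplitudes) at the optimum. `bootstrap`
resamples whole curves (stratified by domain) with replacement and
refits, reporting t-based intervals on the log₁₀K_d scale with
n_curves−1 degrees of freedom. Curve-level case resampling was chosen
over pointwise residual resampling deliberately: every point of a curve
shares the same noisy apo anchor, so within-curve errors are correlated
and partly absorbed into the fitted amplitudes; residual-level
resampling consequently understates the K_d uncertainty by roughly 30%
(measured 95%-interval coverage ~65% against the generator, vs ~87%
for the curve-level scheme over 30 replicates — the remaining gap to
nominal reflects a small per-design estimator bias of the magnitude-CSP
pipeline). A singular Jacobian degrades asymptotic to bootstrap with a
warning.

## EXSY kinetics

The buildup model assumes two-state exchange and neglects differential
longitudinal relaxation between conformers (their R1 values are taken as
equal, so relaxation cancels from the ratio); cross-relaxation/NOE
contamination of the cross-peaks is likewise ignored. Convention: k_tc
is trans→cis and k_ct is cis→trans, so the plateau k_tc/k_ct equals the
cis:trans population ratio (≈9:91 for a phosphorylated Thr-Pro bond) —
the direction labels are stated in every output because the opposite
convention also circulates. Rates are fitted on a log scale from ratio
curves (not raw intensities), multi-started over k_EX ∈ {0.1, 1, 10,
100} s⁻¹ crossed with cis fractions {0.05, 0.1, 0.2}. Schedules that do
not bracket 1/k_EX (at least one point below it and one beyond 3/k_EX)
produce an identifiability warning. The detectability window 0.1–100 s⁻¹
is inclusive at both ends. An all-zero curve is diagnosed as "no
exchange", not an error.

## Bivalency thermodynamics

fold = K_d,ref/K_d and ΔΔG° = −RT ln(fold), with
R = 1.9872×10⁻³ kcal·mol⁻¹·K⁻¹ and T defaulting to 298.15 K (the
experiments run at 25 °C). Folds are kept at full precision internally;
any rounding ("~90-fold") happens only at display. The additivity row of
a ledger multiplies component folds and sums their ΔΔG° — exact by the
logarithm identity, meaningful only if the components are independent.

## Synthetic data

The generator emulates the study design: P₀ = 100 μM; 10 titration
points from 0 to a maximum chosen to reach ≥80% site saturation
(5·K_d-scale + 2·P₀); 12 responsive residues for single-site scenarios
and 10 per domain for two-site; per-dimension saturation amplitudes
drawn uniformly from ±0.3 ppm; fast-exchange averaging (observed shift
= apo + amplitude × occupancy); additive Gaussian peak-position noise of
sd 0.005 ppm on ¹H and 0.005/0.152 ppm on ¹⁵N, so combined-Δ noise is
isotropic. EXSY curves use the experimental mixing-time schedules
(20–500 ms) with multiplicative Gaussian noise. Randomness is split into
per-purpose, per-residue streams keyed on the recorded seed, so adding a
residue or redrawing noise never perturbs other draws; apo positions and
amplitudes live in the `GroundTruth`, so re-simulating with a new seed
changes only the noise.

Not emulated: peak overlap and assignment transfer, intermediate- or
slow-exchange line broadening, baseline/phasing artifacts, per-residue
amplitude correlations, and concentration errors in the titrant.
Passing recovery tests therefore demonstrate correctness of the
estimators under the stated noise model, not robustness to those
real-data pathologies.

Scenario constants: the two-site truth uses K_d,W = 257 μM and
K_d,I = 75 μM (the measured phospho-hydrophobic-motif affinities); the
single-site truth uses K_d = 154 μM with the same concentration design;
the EXSY truth uses k_EX = 29.6 s⁻¹ split 91:9.

## Problem sizes in tests and the acceptance script

The test suite runs the recovery study at 50 seeded replicates per model
(the acceptance script uses 20), the oracle grid at 10⁴ points, and the
bootstrap coverage check at 30 replicates × 120 resamples — sizes chosen
so the full suite completes in well under a minute per heavy test while
keeping Monte-Carlo noise far below the asserted margins.

## Known limitations

- K_d values approaching the tight-binding regime (K_d ≲ P₀/5) are
  poorly determined by shift-only analysis; lineshape fitting is the
  appropriate tool there and is out of scope.
- The two-site model assumes independent sites; cooperative or
  ternary-exclusion models are not implemented.
- The EXSY model's equal-relaxation assumption biases rates when the
  conformers' R1 differ appreciably.
- Bootstrap intervals inherit the smallness of the curve count: with ~12
  curves the t-based intervals are approximate, and a small downward
  bias of the magnitude-CSP K_d estimator remains uncorrected.
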